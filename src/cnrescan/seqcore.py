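"""Nucleotide sequence primitives, FASTA I/O and the glocal aligner.

Coordinates are 0-based half-open internally; everything written to reports
is 1-based inclusive.  Sequences are stored upper-case over the alphabet
{A, C, G, T, N}.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _align

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class NucSequence:
    """An identified nucleotide sequence over {A, C, G, T, N}.

    Lower-case input is accepted and canonicalized to upper case; the
    ``source`` field records provenance (file of origin, generator spec,
    or a note that case folding occurred).
    """

    id: str
    bases: str
    source: str | None = None

    def __post_init__(self):
        up = self.bases.upper()
        if up != self.bases:
            object.__setattr__(self, "bases", up)
            note = "case-folded"
            src = f"{self.source}; {note}" if self.source else note
            object.__setattr__(self, "source", src)
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        return _align.encode(self.bases)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores for the glocal aligner.

    A gap of length L costs ``gap_open + L * gap_extend``.  The defaults
    (+1/-1, open -5, extend -2) are this package's own; they are echoed into
    every report header so that scores are interpretable.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GlocalAlignment:
    """One optimal placement of a fully-aligned query inside a subject.

    ``subject_start``/``subject_end`` are 1-based inclusive on the subject;
    for a query aligned entirely to gaps the span is empty and
    ``subject_end == subject_start - 1``.
    """

    score: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def query_coverage(self) -> bool:
        """True by construction: every query base appears in the alignment."""
        return True


def revcomp(seq: NucSequence) -> NucSequence:
    """Reverse complement; N maps to N."""
    return NucSequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1], seq.source)


def revcomp_str(bases: str) -> str:
    bad = set(bases.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    return bases.upper().translate(_COMPLEMENT)[::-1]


def hamming(a: NucSequence | str, b: NucSequence | str) -> int:
    """Number of differing positions between equal-length sequences.

    N is treated as matching nothing, so N-vs-N counts as a mismatch.
    """
    sa = a.bases if isinstance(a, NucSequence) else a.upper()
    sb = b.bases if isinstance(b, NucSequence) else b.upper()
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    ca, cb = _align.encode(sa), _align.encode(sb)
    return int(np.sum((ca != cb) | (ca == 4) | (cb == 4)))


def glocal_align(
    query: NucSequence | str,
    subject: NucSequence | str,
    scheme: ScoringScheme | None = None,
) -> GlocalAlignment:
    """Optimal query-global / subject-local alignment.

    The full query is aligned against some contiguous subject region; subject
    bases outside that region cost nothing.  Ties are broken toward the
    smallest subject start, then the shortest span.
    """
    scheme = scheme or ScoringScheme()
    qs = query.bases if isinstance(query, NucSequence) else query.upper()
    ss = subject.bases if isinstance(subject, NucSequence) else subject.upper()
    if not qs:
        raise ValueError("empty query")
    score, s0, s1 = _align.glocal_best(
        _align.encode(ss), _align.encode(qs),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
    )
    aq, asub = _global_traceback(qs, ss[s0:s1], scheme)
    return GlocalAlignment(
        score=int(score),
        subject_start=s0 + 1,
        subject_end=s1,
        aligned_query=aq,
        aligned_subject=asub,
    )


def glocal_score(
    query: NucSequence | str,
    subject: NucSequence | str,
    scheme: ScoringScheme | None = None,
) -> int:
    """Score-only variant of :func:`glocal_align`."""
    scheme = scheme or ScoringScheme()
    qs = query.bases if isinstance(query, NucSequence) else query.upper()
    ss = subject.bases if isinstance(subject, NucSequence) else subject.upper()
    if not qs:
        raise ValueError("empty query")
    score, _, _ = _align.glocal_best(
        _align.encode(ss), _align.encode(qs),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
    )
    return int(score)


def glocal_scores_batch(
    queries: Sequence[str],
    subject: NucSequence | str,
    scheme: ScoringScheme | None = None,
) -> np.ndarray:
    """Best glocal score of each equal-length query against one subject."""
    scheme = scheme or ScoringScheme()
    ss = subject.bases if isinstance(subject, NucSequence) else subject.upper()
    if not queries:
        return np.empty(0, dtype=np.int32)
    m = len(queries[0])
    if any(len(q) != m for q in queries):
        raise ValueError("batch queries must share one length")
    qt = np.empty((m, len(queries)), dtype=np.int8)
    for k, q in enumerate(queries):
        qt[:, k] = _align.encode(q.upper())
    return _align.glocal_score_multi(
        _align.encode(ss), qt,
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
    )


def _global_traceback(query: str, subject: str, scheme: ScoringScheme):
    """Affine-gap global alignment with traceback, used only on the short
    subject slice located by the DP kernel; returns gapped strings."""
    m, n = len(query), len(subject)
    neg = -(10**8)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.full((n + 1, m + 1), neg, dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = go + j * ge
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = go + i * ge
        H[i, 0] = F[i, 0]
    qc, sc = _align.encode(query), _align.encode(subject)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + go + ge, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go + ge, F[i - 1, j] + ge)
            s = scheme.match if (sc[i - 1] == qc[j - 1] and sc[i - 1] < 4) else scheme.mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, E[i, j], F[i, j])
    aq, asub = [], []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                s = scheme.match if (sc[i - 1] == qc[j - 1] and sc[i - 1] < 4) else scheme.mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    aq.append(query[j - 1])
                    asub.append(subject[i - 1])
                    i, j = i - 1, j - 1
                    continue
            if H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aq.append(query[j - 1])
            asub.append("-")
            if not (j > 1 and E[i, j] == E[i, j - 1] + ge):
                state = "H"
            j -= 1
        else:
            aq.append("-")
            asub.append(subject[i - 1])
            if not (i > 1 and F[i, j] == F[i - 1, j] + ge):
                state = "H"
            i -= 1
    return "".join(reversed(aq)), "".join(reversed(asub))


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (possibly wrapped) FASTA file into NucSequence records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        records.append(NucSequence(rec.id, str(rec.seq), source=str(path)))
    return records


def write_fasta(records: Iterable[NucSequence], path: str | Path) -> None:
    """Write records as FASTA wrapped at 80 columns."""
    recs = [SeqRecord(Seq(r.bases), id=r.id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")
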