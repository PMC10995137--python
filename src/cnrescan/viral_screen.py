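"""Screening viral genomes for cNRE-like signatures.

Each viral genome is scored by the best query-global / subject-local
alignment of the 32-nt motif, in both orientations.  Significance comes
from an empirical permutation null: 1000 random 32-mers (the same set for
every virus) are aligned to each genome; a hit is significant when its
score exceeds the 95th percentile of that genome's null scores.  The full
screen ranks all viruses by score, keeps the top 2000, reduces to the best
virus per family, computes empirical p-values for the survivors and
retains those with p <= 0.05 — in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .motif import TripartiteMotif
from .seqcore import (
    NucSequence,
    ScoringScheme,
    glocal_align,
    glocal_scores_batch,
    hamming,
    revcomp_str,
)

DEFAULT_NULL_N = 1000
DEFAULT_TOP_K = 2000
DEFAULT_ALPHA = 0.05
NULL_PERCENTILE = 95.0


@dataclass(frozen=True)
class GlocalHit:
    """Best glocal placement of the motif on one viral genome.

    ``oriented_sequence`` reads in motif orientation (reverse-complemented
    for minus-strand hits).  ``mismatches`` is the Hamming distance of the
    oriented hit to the consensus when the hit is ungapped and full length,
    else None.
    """

    virus_id: str
    family: str
    score: int
    start: int  # 1-based inclusive on the viral plus strand
    end: int
    strand: str
    oriented_sequence: str
    mismatches: int | None = None
    empirical_p: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class NullDistribution:
    """Per-virus score distributions of one shared set of random 32-mers."""

    n: int
    seed: int
    length: int
    sequences: tuple[str, ...]
    scores: dict[str, np.ndarray]  # virus_id -> n scores


def random_32mers(
    n: int, seed: int, length: int = 32, gc: float | None = None
) -> list[str]:
    """n iid random DNA sequences of the motif length.  Uniform base
    composition by default; pass ``gc`` for a GC-matched null."""
    rng = np.random.default_rng(seed)
    if gc is None:
        p = None
    else:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(np.array(list("ACGT")), size=(n, length), p=p)
    return ["".join(row) for row in draws]


def best_glocal_hit(
    motif: TripartiteMotif,
    virus: NucSequence,
    scheme: ScoringScheme | None = None,
    family: str = "unclassified",
) -> GlocalHit:
    """Maximum over both motif orientations of the glocal score; ties go to
    the plus strand, then the smallest start."""
    scheme = scheme or ScoringScheme()
    best = None
    for strand, query in (("+", motif.bases), ("-", revcomp_str(motif.bases))):
        aln = glocal_align(query, virus, scheme)
        key = (-aln.score, 0 if strand == "+" else 1, aln.subject_start)
        if best is None or key < best[0]:
            best = (key, strand, aln)
    _, strand, aln = best
    frag = virus.bases[aln.subject_start - 1 : aln.subject_end]
    oriented = frag if strand == "+" else revcomp_str(frag)
    gapless = "-" not in aln.aligned_query and "-" not in aln.aligned_subject
    mism = (
        hamming(oriented, motif.bases)
        if gapless and len(oriented) == len(motif.consensus)
        else None
    )
    return GlocalHit(
        virus_id=virus.id,
        family=family,
        score=aln.score,
        start=aln.subject_start,
        end=aln.subject_end,
        strand=strand,
        oriented_sequence=oriented,
        mismatches=mism,
    )


def build_null(
    viruses: list[NucSequence],
    scheme: ScoringScheme | None = None,
    n: int = DEFAULT_NULL_N,
    seed: int = 0,
) -> NullDistribution:
    """Score the same ``n`` random 32-mers against every virus."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scheme = scheme or ScoringScheme()
    seqs = random_32mers(n, seed)
    scores = {
        v.id: np.asarray(glocal_scores_batch(seqs, v, scheme), dtype=np.int32)
        for v in viruses
    }
    return NullDistribution(n=n, seed=seed, length=32, sequences=tuple(seqs), scores=scores)


def empirical_p(score: float, null_scores: np.ndarray) -> tuple[float, bool]:
    """Permutation p-value with the +1 finite-sample correction,
    p = (1 + #{null >= score}) / (n + 1), and the percentile significance
    flag: significant iff score strictly exceeds the 95th percentile
    (linear interpolation) of the null scores."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("null_scores must be non-empty")
    n = null_scores.size
    p = (1 + int(np.sum(null_scores >= score))) / (n + 1)
    sig = score > float(np.percentile(null_scores, NULL_PERCENTILE))
    return p, sig


def screen(
    viruses: list[NucSequence],
    taxonomy: dict[str, str] | None = None,
    motif: TripartiteMotif | None = None,
    scheme: ScoringScheme | None = None,
    n: int = DEFAULT_NULL_N,
    seed: int = 0,
    top_k: int = DEFAULT_TOP_K,
    alpha: float = DEFAULT_ALPHA,
) -> list[GlocalHit]:
    """Full screen with the published order of operations: rank by best
    score, keep the top ``top_k``, reduce to the best virus per family,
    compute empirical p-values for the survivors, retain p <= alpha.
    The null distribution is built only for the per-family survivors."""
    from .motif import cnre_reference

    if not viruses:
        return []
    taxonomy = taxonomy or {}
    motif = motif or cnre_reference()
    scheme = scheme or ScoringScheme()

    hits = [
        best_glocal_hit(motif, v, scheme, family=taxonomy.get(v.id, "unclassified"))
        for v in viruses
    ]
    # rank by score, ties by virus id (stable, reproducible)
    hits.sort(key=lambda h: (-h.score, h.virus_id))
    hits = hits[:top_k]

    by_family: dict[str, GlocalHit] = {}
    for h in hits:  # hits already ranked, first seen per family wins
        by_family.setdefault(h.family, h)
    survivors = sorted(by_family.values(), key=lambda h: (-h.score, h.virus_id))

    vmap = {v.id: v for v in viruses}
    null = build_null([vmap[h.virus_id] for h in survivors], scheme, n=n, seed=seed)
    out = []
    for h in survivors:
        p, sig = empirical_p(h.score, null.scores[h.virus_id])
        if p <= alpha:
            out.append(replace(h, empirical_p=p, significant=sig))
    return out


def hits_to_frame(hits: list[GlocalHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                virus=h.virus_id, family=h.family, score=h.score, start=h.start,
                end=h.end, strand=h.strand, sequence=h.oriented_sequence,
                mismatches=h.mismatches, p=h.empirical_p, significant=h.significant,
            )
            for h in hits
        ],
        columns=[
            "virus", "family", "score", "start", "end", "strand",
            "sequence", "mismatches", "p", "significant",
        ],
    )
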