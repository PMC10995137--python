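"""The tripartite cNRE motif, its named promoter mutations, and multimer
constructs.

The reference element is the 32-bp complex Nuclear Receptor Element (cNRE)
of the quail SMyHC III promoter: three purine-rich hexad half-sites —
Hexad A (AGGACA, a VDRE half-site), Hexad B (AGGGGA, a RARE half-site) and
Hexad C (GGCGGA, an atrial activator) — separated by short spacers.  The
motif is a consensus plus interval structure, not a weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .seqcore import NucSequence, hamming, revcomp_str

CNRE_CONSENSUS = "GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT"

#: 1-based inclusive position of the first/last hexad base ("position 3 to 29").
HEXAD_SPAN = (3, 29)


@dataclass(frozen=True)
class Hexad:
    name: str
    start: int  # 1-based inclusive on the consensus
    end: int

    def slice(self):
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class TripartiteMotif:
    """A 32-nt consensus with three named, disjoint, ordered hexads."""

    consensus: NucSequence
    hexads: tuple[Hexad, Hexad, Hexad]

    def __post_init__(self):
        if len(self.consensus) != 32:
            raise ValueError("consensus must be 32 nt")
        names = [h.name for h in self.hexads]
        if names != sorted(names) or len(set(names)) != 3:
            raise ValueError("hexads must be three distinct ordered names")
        prev_end = 0
        for h in self.hexads:
            if h.end - h.start + 1 != 6:
                raise ValueError(f"hexad {h.name} is not 6 nt")
            if h.start <= prev_end:
                raise ValueError("hexads must be disjoint and ordered")
            prev_end = h.end

    @property
    def bases(self) -> str:
        return self.consensus.bases

    def hexad_sequence(self, name: str) -> str:
        for h in self.hexads:
            if h.name == name:
                return self.bases[h.slice()]
        raise KeyError(name)

    @property
    def spacers(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals of the consensus outside the hexads."""
        out, pos = [], 1
        for h in self.hexads:
            if h.start > pos:
                out.append((pos, h.start - 1))
            pos = h.end + 1
        if pos <= len(self.consensus):
            out.append((pos, len(self.consensus)))
        return out

    def hexad_mismatches(self, oriented: str) -> tuple[int, ...]:
        """Per-hexad Hamming counts of a full-length oriented hit."""
        if len(oriented) != len(self.consensus):
            raise ValueError("oriented sequence must be full length")
        return tuple(
            hamming(oriented[h.slice()], self.bases[h.slice()]) for h in self.hexads
        )


def cnre_reference() -> TripartiteMotif:
    """The reference cNRE: GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT with hexads at
    3-8 (AGGACA), 12-17 (AGGGGA) and 24-29 (GGCGGA)."""
    return TripartiteMotif(
        consensus=NucSequence("cNRE", CNRE_CONSENSUS),
        hexads=(Hexad("A", 3, 8), Hexad("B", 12, 17), Hexad("C", 24, 29)),
    )


def load_motif(path: str | Path) -> TripartiteMotif:
    """Load a motif definition from a small YAML document
    (consensus + hexad intervals)."""
    doc = yaml.safe_load(Path(path).read_text())
    hexads = tuple(
        Hexad(name, int(iv[0]), int(iv[1]))
        for name, iv in sorted(doc["hexads"].items())
    )
    return TripartiteMotif(NucSequence("motif", doc["consensus"]), hexads)


@dataclass(frozen=True)
class NamedMutation:
    """A set of single-base edits on the consensus, as used in the reporter
    constructs: Mut A/B/C hit the first bases of each hexad, Mut S hits the
    B-C spacer."""

    name: str
    edits: tuple[tuple[int, str, str], ...]  # (1-based position, old, new)


MUTATIONS: dict[str, NamedMutation] = {
    "MutA": NamedMutation(
        "MutA",
        tuple((p, o, n) for p, o, n in zip(range(3, 9), "AGGACA", "GTCGAC")),
    ),
    "MutB": NamedMutation("MutB", ((12, "A", "T"), (13, "G", "T"))),
    "MutC": NamedMutation("MutC", ((24, "G", "T"), (25, "G", "T"))),
    "MutS": NamedMutation("MutS", ((18, "C", "T"), (19, "A", "T"))),
}


def apply_mutation(seq: NucSequence, mut: NamedMutation, offset: int = 1) -> NucSequence:
    """Apply a named mutation to ``seq`` where the consensus starts at
    1-based ``offset``.  Each edit's old base is verified against the
    sequence, which guards against coordinate drift and makes a second
    application fail loudly."""
    chars = list(seq.bases)
    for pos, old, new in mut.edits:
        i = offset - 1 + pos - 1
        if i < 0 or i >= len(chars):
            raise ValueError(f"{mut.name}: edit position {pos} outside sequence")
        if chars[i] != old:
            raise ValueError(
                f"{mut.name}: expected {old} at consensus position {pos}, "
                f"found {chars[i]} (already mutated or wrong offset?)"
            )
        chars[i] = new
    return NucSequence(f"{seq.id}_{mut.name}", "".join(chars), seq.source)


def tandem_construct(
    motif: TripartiteMotif,
    n: int,
    prefix: str = "",
    suffix: str = "",
) -> NucSequence:
    """``prefix + n x consensus + suffix`` — e.g. the 5x tandem element
    cloned upstream of the vmhc promoter."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return NucSequence(f"{n}x{motif.consensus.id}", prefix + motif.bases * n + suffix)


@dataclass(frozen=True)
class PrimerMatch:
    offset: int  # 1-based position of primer 5' end on the plus strand of context
    strand: str
    mismatches: int


def primer_concordance(context: NucSequence, primer: NucSequence) -> PrimerMatch:
    """Best ungapped placement of a primer on either strand of a context.

    Reports the best placement even when poor; used to validate that printed
    mutagenesis primers tile the promoter context they were designed for.
    """
    if len(primer) > len(context):
        raise ValueError("primer longer than context")
    best: PrimerMatch | None = None
    for strand, p in (("+", primer.bases), ("-", revcomp_str(primer.bases))):
        for off in range(len(context) - len(p) + 1):
            mm = hamming(context.bases[off : off + len(p)], p)
            cand = PrimerMatch(off + 1, strand, mm)
            if best is None or cand.mismatches < best.mismatches:
                best = cand
    assert best is not None
    return best


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cnrescan").joinpath("data", name)))


def table2_primers() -> dict[str, NucSequence]:
    """The printed mutagenesis primers (sense and antisense), verbatim."""
    from .seqcore import read_fasta

    return {r.id: r for r in read_fasta(_data_path("table2_primers.fasta"))}


def fivex_oligo() -> NucSequence:
    """The printed 171-nt sense oligonucleotide carrying five tandem cNRE
    copies (the third copy carries one substitution, stored verbatim)."""
    from .seqcore import read_fasta

    recs = {r.id: r for r in read_fasta(_data_path("fivex_cnre.fasta"))}
    return recs["5xcNRE_sense"]


def reconstructed_promoter_context() -> NucSequence:
    """Synthetic local promoter context around the cNRE, assembled from the
    overlapping printed primer fragments (5'-cttgc upstream, ggggctgg-3'
    downstream).  Reconstructed for primer-concordance checks only; it is
    not a deposited promoter sequence."""
    return NucSequence("promoter_context_synthetic", "CTTGC" + CNRE_CONSENSUS + "GGGGCTGG")
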