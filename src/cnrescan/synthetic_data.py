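"""Seeded generators for every input class, with exact ground truth.

Each generator is a pure function of its spec and seed: the same call
returns byte-identical output.  Mismatches are realized by sampling
distinct positions without replacement and resampling each base to a
*different* nucleotide, so the realized Hamming count always equals the
requested count.  Truth tables carry exact coordinates, strands and
realized mismatch counts, sufficient to score the sensitivity and
specificity of every downstream stage without re-reading the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motif import CNRE_CONSENSUS, TripartiteMotif, cnre_reference
from .seqcore import NucSequence, revcomp_str

BASES = np.array(list("ACGT"))
TELOMERIC_UNIT = "TTAGGG"  # complement of the 5'-GGGTTA-3' telomeric hexad


@dataclass(frozen=True)
class CopySpec:
    """One planted motif copy: position (1-based start, or None for random),
    strand, per-hexad mismatch counts and spacer mismatch count."""

    position: int | None = None
    strand: str = "+"
    hexad_mismatches: tuple[int, int, int] = (0, 0, 0)
    spacer_mismatches: int = 0

    @property
    def total(self) -> int:
        return sum(self.hexad_mismatches) + self.spacer_mismatches


@dataclass(frozen=True)
class DecoySpec:
    kind: str  # telomeric_repeat | shuffled_cnre | hexad_violator
    position: int | None = None


@dataclass(frozen=True)
class PlantSpec:
    length: int = 100_000
    gc: float = 0.5
    copies: tuple[CopySpec, ...] = ()
    decoys: tuple[DecoySpec, ...] = ()
    seed: int = 0


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=length, p=p)


def _mutate_positions(
    rng: np.random.Generator, seq: list[str], positions: list[int], k: int
) -> None:
    """Substitute k distinct positions (0-based, within ``positions``) to a
    different base each."""
    for i in rng.choice(len(positions), size=k, replace=False):
        pos = positions[int(i)]
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq[pos] = choices[int(rng.integers(3))]


def _realize_copy(rng: np.random.Generator, motif: TripartiteMotif, spec: CopySpec) -> str:
    seq = list(motif.bases)
    hexad_pos = []
    for h, k in zip(motif.hexads, spec.hexad_mismatches):
        pos = list(range(h.start - 1, h.end))
        hexad_pos.extend(pos)
        _mutate_positions(rng, seq, pos, k)
    spacer_pos = [i for i in range(len(seq)) if i not in set(hexad_pos)]
    _mutate_positions(rng, seq, spacer_pos, spec.spacer_mismatches)
    return "".join(seq)


def _realize_decoy(rng: np.random.Generator, motif: TripartiteMotif, kind: str) -> str:
    if kind == "telomeric_repeat":
        return TELOMERIC_UNIT * 5  # a 30-nt telomeric hexamer array
    if kind == "shuffled_cnre":
        while True:
            perm = "".join(rng.permutation(list(motif.bases)))
            mms = motif.hexad_mismatches(perm)
            if max(mms) >= 2:  # must fail the hexad filter
                return perm
    if kind == "hexad_violator":
        seq = list(motif.bases)
        h = motif.hexads[int(rng.integers(3))]
        _mutate_positions(rng, seq, list(range(h.start - 1, h.end)), 2)
        return "".join(seq)
    raise ValueError(f"unknown decoy kind {kind!r}")


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    size: int,
    position: int | None,
) -> int:
    """Find a 0-based start for a ``size``-long insert avoiding overlaps."""
    if position is not None:
        start = position - 1
        if start < 0 or start + size > length:
            raise ValueError(f"requested position {position} outside genome")
        if any(start < e and start + size > s for s, e in occupied):
            raise ValueError(f"requested position {position} overlaps another plant")
        return start
    for _ in range(10_000):
        start = int(rng.integers(0, length - size + 1))
        if not any(start < e and start + size > s for s, e in occupied):
            return start
    raise ValueError("could not place insert: spec overcrowded")


def gen_genome(
    spec: PlantSpec, motif: TripartiteMotif | None = None
) -> tuple[NucSequence, pd.DataFrame, pd.DataFrame]:
    """Random-background genome with planted copies and decoys.

    Returns (genome, copy_truth, decoy_truth); truth coordinates are
    1-based inclusive on the plus strand.
    """
    motif = motif or cnre_reference()
    m = len(motif.consensus)
    footprint = len(spec.copies) * m + sum(
        30 if d.kind == "telomeric_repeat" else m for d in spec.decoys
    )
    if spec.length < footprint:
        raise ValueError("genome length smaller than total plant footprint")
    rng = np.random.default_rng(spec.seed)
    genome = _random_background(rng, spec.length, spec.gc)
    occupied: list[tuple[int, int]] = []

    copy_rows = []
    for c in spec.copies:
        insert = _realize_copy(rng, motif, c)
        if c.strand == "-":
            insert = revcomp_str(insert)
        start = _place(rng, occupied, spec.length, m, c.position)
        occupied.append((start, start + m))
        genome[start : start + m] = list(insert)
        ha, hb, hc = c.hexad_mismatches
        copy_rows.append(
            dict(start=start + 1, end=start + m, strand=c.strand,
                 hexA_mm=ha, hexB_mm=hb, hexC_mm=hc,
                 spacer_mm=c.spacer_mismatches, total_mm=c.total,
                 passes_filter=max(c.hexad_mismatches) <= 1)
        )

    decoy_rows = []
    for d in spec.decoys:
        insert = _realize_decoy(rng, motif, d.kind)
        start = _place(rng, occupied, spec.length, len(insert), d.position)
        occupied.append((start, start + len(insert)))
        genome[start : start + len(insert)] = list(insert)
        decoy_rows.append(dict(kind=d.kind, start=start + 1, end=start + len(insert)))

    seq = NucSequence(f"synthetic_genome_seed{spec.seed}", "".join(genome),
                      source="synthetic_data.gen_genome")
    copy_truth = pd.DataFrame(
        copy_rows,
        columns=["start", "end", "strand", "hexA_mm", "hexB_mm", "hexC_mm",
                 "spacer_mm", "total_mm", "passes_filter"],
    )
    decoy_truth = pd.DataFrame(decoy_rows, columns=["kind", "start", "end"])
    return seq, copy_truth, decoy_truth


def benchmark_spec(seed: int, length: int = 1_000_000,
                   n_copies: int = 20, n_decoys: int = 20) -> PlantSpec:
    """The standard scan benchmark: planted copies cycling through mismatch
    classes (clean, spacer-only, 1-per-hexad, hexad violators) on both
    strands, plus a decoy mix of telomeric arrays, shuffles and hexad
    violators."""
    classes = [
        CopySpec(strand="+", hexad_mismatches=(0, 0, 0), spacer_mismatches=0),
        CopySpec(strand="-", hexad_mismatches=(0, 0, 0), spacer_mismatches=3),
        CopySpec(strand="+", hexad_mismatches=(1, 0, 0), spacer_mismatches=1),
        CopySpec(strand="-", hexad_mismatches=(0, 1, 1), spacer_mismatches=2),
        CopySpec(strand="+", hexad_mismatches=(1, 1, 1), spacer_mismatches=4),
        CopySpec(strand="-", hexad_mismatches=(2, 0, 0), spacer_mismatches=0),  # fails filter
        CopySpec(strand="+", hexad_mismatches=(0, 2, 1), spacer_mismatches=2),  # fails filter
    ]
    decoy_kinds = ["telomeric_repeat", "shuffled_cnre", "hexad_violator"]
    return PlantSpec(
        length=length,
        gc=0.5,
        copies=tuple(classes[i % len(classes)] for i in range(n_copies)),
        decoys=tuple(DecoySpec(decoy_kinds[i % 3]) for i in range(n_decoys)),
        seed=seed,
    )


def gen_virus(
    length: int,
    planted_mismatches: int | None = None,
    family: str = "unclassified",
    seed: int = 0,
    virus_id: str | None = None,
    motif: TripartiteMotif | None = None,
) -> tuple[NucSequence, dict]:
    """Random viral genome with one optional planted degenerate motif copy
    at a random recorded position and strand.  ``planted_mismatches`` are
    spread uniformly over the 32 positions (None = no plant)."""
    motif = motif or cnre_reference()
    m = len(motif.consensus)
    if planted_mismatches is not None and length < m:
        raise ValueError("virus too short to plant a copy")
    rng = np.random.default_rng(seed)
    genome = _random_background(rng, length, 0.5)
    truth: dict = dict(virus_id=virus_id or f"virus_seed{seed}", family=family,
                       planted=False)
    if planted_mismatches is not None:
        seq = list(motif.bases)
        _mutate_positions(rng, seq, list(range(m)), planted_mismatches)
        insert = "".join(seq)
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            insert = revcomp_str(insert)
        start = int(rng.integers(0, length - m + 1))
        genome[start : start + m] = list(insert)
        truth.update(planted=True, start=start + 1, end=start + m,
                     strand=strand, mismatches=planted_mismatches)
    seq_out = NucSequence(truth["virus_id"], "".join(genome),
                          source="synthetic_data.gen_virus")
    return seq_out, truth


def gen_energy_profiles(
    planted_starts: list[int],
    effect: float = 10.0,
    noise_sd: float = 1.0,
    n_receptors: int = 3,
    seed: int = 0,
) -> tuple[list, list[int]]:
    """ddG profiles with baseline ~ Normal(0, noise_sd) at every start 1..27
    and the planted starts shifted down by ``effect`` (stronger predicted
    binding) in every receptor."""
    from .energy_profile import MAX_START, EnergyProfile

    if any(not (1 <= s <= MAX_START) for s in planted_starts):
        raise ValueError("planted starts must lie in [1, 27]")
    rng = np.random.default_rng(seed)
    profiles = []
    for r in range(n_receptors):
        vals = {s: float(rng.normal(0.0, noise_sd)) for s in range(1, MAX_START + 1)}
        for s in planted_starts:
            vals[s] -= effect
        profiles.append(EnergyProfile(f"receptor{r + 1}", vals))
    return profiles, sorted(planted_starts)


def gen_titration(
    kd: float = 100.0,
    hill_n: float = 1.0,
    r_free: float = 0.05,
    r_bound: float = 0.25,
    n_points: int = 12,
    noise: float = 0.02,
    replicates: int = 1,
    seed: int = 0,
    c_min: float = 2.0,
    c_max: float = 2.0e6,
):
    """Noisy Hill titrations over the standard serial-dilution design
    (2 nM to 2 mM, log-spaced).  ``noise`` is the Gaussian noise standard
    deviation as a fraction of the binding amplitude |r_bound - r_free|."""
    from .binding_fit import TitrationCurve, hill_model

    if n_points < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(c_min, c_max, n_points)
    amp = abs(r_bound - r_free)
    curves = []
    for rep in range(replicates):
        clean = hill_model(conc, kd, hill_n, r_free, r_bound)
        noisy = clean + rng.normal(0.0, noise * amp, size=n_points)
        curves.append(
            TitrationCurve("synthetic_probe", conc, noisy, replicate_id=f"r{rep + 1}")
        )
    return curves


def spec_from_yaml(path: str | Path) -> PlantSpec:
    """Load a PlantSpec from a YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    copies = tuple(
        CopySpec(
            position=c.get("position"),
            strand=c.get("strand", "+"),
            hexad_mismatches=tuple(c.get("hexad_mismatches", (0, 0, 0))),
            spacer_mismatches=int(c.get("spacer_mismatches", 0)),
        )
        for c in doc.get("copies", [])
    )
    decoys = tuple(
        DecoySpec(kind=d["kind"], position=d.get("position"))
        for d in doc.get("decoys", [])
    )
    return PlantSpec(
        length=int(doc.get("length", 100_000)),
        gc=float(doc.get("gc", 0.5)),
        copies=copies,
        decoys=decoys,
        seed=int(doc.get("seed", 0)),
    )
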