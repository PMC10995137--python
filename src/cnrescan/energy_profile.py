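"""Hexad calling from binding free-energy (ddG) profiles.

Upstream molecular-dynamics / Poisson-Boltzmann machinery produces, for
each nuclear receptor, one ddG value per candidate hexad start position
along the 32-nt element (starts 1..27; lower ddG = stronger predicted
binding).  This module does the statistical tail: pool values across
receptors, take the 10th percentile as a threshold, call hexad starts that
fall strictly below it, and score per-nucleotide hexad participation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MAX_START = 27  # last start where a 6-mer fits inside the 32-nt element
ELEMENT_LENGTH = 32
HEXAD_LENGTH = 6
DEFAULT_PERCENTILE = 10.0


@dataclass(frozen=True)
class EnergyProfile:
    receptor_id: str
    values: dict[int, float]  # hexad start (1-based) -> ddG

    def __post_init__(self):
        for s, v in self.values.items():
            if not (1 <= s <= MAX_START):
                raise ValueError(f"hexad start {s} outside [1, {MAX_START}]")
            if not math.isfinite(v):
                raise ValueError(f"non-finite ddG at start {s}")


def pooled_threshold(
    profiles: list[EnergyProfile], percentile: float = DEFAULT_PERCENTILE
) -> float:
    """The given percentile (linear interpolation) of all ddG values pooled
    across receptors."""
    pool = np.array([v for p in profiles for v in p.values.values()], dtype=float)
    if pool.size < 2:
        raise ValueError("need at least 2 pooled ddG values")
    return float(np.percentile(pool, percentile))


def call_hexads(profile: EnergyProfile, threshold: float) -> list[int]:
    """Start positions with ddG strictly below the threshold, ascending."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return sorted(s for s, v in profile.values.items() if v < threshold)


def participation_scores(selected_starts: list[int]) -> np.ndarray:
    """Per-nucleotide counts over positions 1..32: how many selected hexads
    cover each nucleotide.  Index 0 of the returned array is position 1."""
    counts = np.zeros(ELEMENT_LENGTH, dtype=int)
    for s in selected_starts:
        if not (1 <= s <= MAX_START):
            raise ValueError(f"start {s} outside [1, {MAX_START}]")
        counts[s - 1 : s - 1 + HEXAD_LENGTH] += 1
    return counts


def read_profiles(path: str | Path) -> list[EnergyProfile]:
    """TSV with columns receptor_id, start, ddG."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for rid, grp in df.groupby("receptor_id", sort=True):
        profiles.append(
            EnergyProfile(str(rid), dict(zip(grp["start"].astype(int), grp["ddG"])))
        )
    return profiles


def write_profiles(profiles: list[EnergyProfile], path: str | Path) -> None:
    rows = [
        dict(receptor_id=p.receptor_id, start=s, ddG=v)
        for p in profiles
        for s, v in sorted(p.values.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_profile(profile: EnergyProfile, threshold: float | None = None, ax=None):
    """Diagnostic plot of one ddG profile (matplotlib optional at runtime)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    starts = sorted(profile.values)
    ax.plot(starts, [profile.values[s] for s in starts], marker="o", lw=1)
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", label="threshold")
        ax.legend()
    ax.set_xlabel("hexad start (position on element)")
    ax.set_ylabel("ddG")
    ax.set_title(profile.receptor_id)
    return ax
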