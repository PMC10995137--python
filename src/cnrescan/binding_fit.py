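"""Hill-model fitting of fluorescence-anisotropy titration curves.

The observed anisotropy of a labelled oligonucleotide titrated with
protein is modelled as a Hill isotherm on total protein concentration
(ligand-depletion-free approximation):

    r(c) = r_free + (r_bound - r_free) * c**n / (Kd**n + c**n)

Parameters are estimated by Levenberg-Marquardt least squares with
asymptotic standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TitrationCurve:
    """One titration series: protein concentrations (nM, ascending) and
    measured anisotropies."""

    probe_id: str
    concentrations: np.ndarray  # nM, strictly positive, sorted ascending
    anisotropy: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.anisotropy, dtype=float)
        if c.shape != a.shape:
            raise ValueError("concentration and anisotropy lengths differ")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) < 0):
            raise ValueError("concentrations must be sorted ascending")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "anisotropy", a)


@dataclass(frozen=True)
class BindingFit:
    """Fitted Hill parameters.  ``kd`` in nM; ``hill_n`` dimensionless;
    ``r_free``/``r_bound`` are the unbound/saturated anisotropy asymptotes."""

    kd: float
    hill_n: float
    r_free: float
    r_bound: float
    stderr: dict[str, float]
    converged: bool
    rss: float


def hill_model(c, kd: float, hill_n: float, r_free: float, r_bound: float):
    """Hill isotherm r(c); c > 0 (nM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    with np.errstate(invalid="ignore"):  # optimizer may probe kd < 0
        cn = c**hill_n
        return r_free + (r_bound - r_free) * cn / (kd**hill_n + cn)


def _initial_guess(c: np.ndarray, r: np.ndarray):
    r_free, r_bound = float(r[0]), float(r[-1])
    half = (r_free + r_bound) / 2.0
    # Kd guess: first concentration where the curve crosses half amplitude
    crossing = c[-1] ** 0.5 * c[0] ** 0.5
    sign = np.sign(r - half)
    idx = np.nonzero(sign[:-1] != sign[1:])[0]
    if idx.size:
        i = int(idx[0])
        crossing = float(np.sqrt(c[i] * c[i + 1]))
    return [crossing, 1.0, r_free, r_bound]


def fit_titration(
    curve: TitrationCurve, p0: list[float] | None = None
) -> BindingFit:
    """Levenberg-Marquardt fit of the Hill model.

    Degenerate (flat) curves yield ``converged=False`` rather than an
    exception; the convergence flag also requires finite standard errors.
    """
    c, r = curve.concentrations, curve.anisotropy
    if c.size < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if p0 is None:
        p0 = _initial_guess(c, r)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat curves: singular covariance
            popt, pcov = curve_fit(hill_model, c, r, p0=p0, method="lm", maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(perr))) and popt[0] > 0
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        perr = np.full(4, np.inf)
        converged = False
    # optimizer contract: never report a fit worse than the starting guess
    rss0 = float(np.sum((r - hill_model(c, *p0)) ** 2))
    rss = float(np.sum((r - hill_model(c, *popt)) ** 2))
    if rss > rss0:
        popt, perr, rss, converged = np.asarray(p0, float), np.full(4, np.inf), rss0, False
    names = ["kd", "hill_n", "r_free", "r_bound"]
    return BindingFit(
        kd=float(popt[0]),
        hill_n=float(popt[1]),
        r_free=float(popt[2]),
        r_bound=float(popt[3]),
        stderr=dict(zip(names, (float(e) for e in perr))),
        converged=converged,
        rss=rss,
    )


def read_titration(path: str | Path, probe_id: str = "probe") -> list[TitrationCurve]:
    """CSV with columns concentration_nM, anisotropy, replicate."""
    df = pd.read_csv(path, comment="#")
    curves = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("concentration_nM")
        curves.append(
            TitrationCurve(
                probe_id,
                grp["concentration_nM"].to_numpy(float),
                grp["anisotropy"].to_numpy(float),
                replicate_id=str(rep),
            )
        )
    return curves


def write_fit(fit: BindingFit, path: str | Path) -> None:
    rows = [
        dict(parameter=k, estimate=getattr(fit, k), stderr=fit.stderr[k])
        for k in ("kd", "hill_n", "r_free", "r_bound")
    ]
    rows.append(dict(parameter="converged", estimate=fit.converged, stderr=""))
    pd.DataFrame(rows).to_csv(path, index=False)
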