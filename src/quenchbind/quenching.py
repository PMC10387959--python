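"""Stern-Volmer quenching analysis.

The Stern-Volmer relation, F0/F = 1 + Ksv[Q] = 1 + Kq*tau0*[Q], links the
fluorescence ratio to the quencher concentration.  The slope Ksv (L/mol)
measures quenching efficiency; dividing by the unquenched fluorophore
lifetime tau0 gives the bimolecular quenching rate constant Kq
(L mol^-1 s^-1).  Kq values far above the diffusion-controlled limit of
about 2e10 L mol^-1 s^-1 cannot arise from collisional (dynamic) quenching
and therefore indicate static quenching through ground-state complex
formation.  A decreasing Ksv with rising temperature corroborates the
static picture (complexes dissociate when heated), while an increase points
to diffusion-driven dynamic quenching.

The regression runs over the quenched points only (q > 0); the zero-quencher
point serves solely as the F0 reference.  On a two-point design the
free-intercept fit therefore reduces to the exact two-point slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .titration_io import TitrationSeries

__all__ = [
    "DEFAULT_TAU0",
    "DIFFUSION_LIMIT_KQ",
    "LinearFit",
    "QuenchingResult",
    "fit_stern_volmer",
    "bimolecular_rate",
    "classify_mechanism",
    "temperature_trend",
]

#: default unquenched fluorophore lifetime of serum albumin, seconds
DEFAULT_TAU0 = 1e-8

#: diffusion-controlled collisional quenching ceiling, L mol^-1 s^-1
DIFFUSION_LIMIT_KQ = 2e10


@dataclass(frozen=True)
class LinearFit:
    """An ordinary-least-squares line y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: tuple[float, ...]

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("linear fit needs at least 2 points")


@dataclass(frozen=True)
class QuenchingResult:
    """Stern-Volmer constants and mechanism call for one temperature."""

    ksv: float  # L/mol
    kq: float  # L mol^-1 s^-1
    tau0: float  # s
    fit: LinearFit
    temperature: float  # K
    mechanism: str | None = None  # "static" | "dynamic"
    intercept_mode: str = "free"
    warnings: tuple[str, ...] = ()


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    resid = y - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if math.isclose(ss_res, 0.0, abs_tol=1e-30) else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(x),
        residuals=tuple(float(r) for r in resid),
    )


def _ols_through_origin(x: np.ndarray, y: np.ndarray) -> LinearFit:
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if math.isclose(ss_res, 0.0, abs_tol=1e-30) else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return LinearFit(
        slope=slope,
        intercept=0.0,
        r_squared=r2,
        n_points=len(x),
        residuals=tuple(float(r) for r in resid),
    )


def fit_stern_volmer(
    series: TitrationSeries,
    intercept_mode: str = "free",
    tau0: float = DEFAULT_TAU0,
) -> QuenchingResult:
    """Fit F0/F against [Q] and return the quenching constants.

    ``intercept_mode='free'`` (default) regresses F0/F on [Q] with a free
    intercept; an intercept deviating from 1 by more than 10% is reported as
    a warning.  ``'fixed_at_one'`` regresses (F0/F - 1) on [Q] through the
    origin.  In both modes Ksv is the slope and Kq = Ksv/tau0.  The
    mechanism field is left unset; see :func:`classify_mechanism`.
    """
    if intercept_mode not in ("free", "fixed_at_one"):
        raise ValueError(f"unknown intercept mode {intercept_mode!r}")
    f0 = series.f0
    pts = series.quenched_points
    q = np.array([p.q_conc for p in pts], dtype=float)
    f = np.array([p.intensity for p in pts], dtype=float)
    if np.any(f <= 0):
        raise ValueError("non-positive corrected intensity in series")
    if len(pts) < 2 or np.unique(q).size < 2:
        raise ValueError(
            "degenerate design: need at least two distinct non-zero concentrations"
        )
    warnings: list[str] = []
    if intercept_mode == "free":
        fit = _ols(q, f0 / f)
        if abs(fit.intercept - 1.0) > 0.1:
            warnings.append(
                f"Stern-Volmer intercept {fit.intercept:.4g} deviates from 1 "
                "by more than 10%"
            )
    else:
        fit = _ols_through_origin(q, f0 / f - 1.0)
    ksv = fit.slope
    return QuenchingResult(
        ksv=ksv,
        kq=bimolecular_rate(ksv, tau0),
        tau0=tau0,
        fit=fit,
        temperature=series.temperature,
        intercept_mode=intercept_mode,
        warnings=tuple(warnings),
    )


def bimolecular_rate(ksv: float, tau0: float = DEFAULT_TAU0) -> float:
    """Bimolecular quenching rate constant Kq = Ksv / tau0 (L mol^-1 s^-1)."""
    if tau0 <= 0:
        raise ValueError(f"non-positive fluorophore lifetime tau0 = {tau0:g} s")
    return ksv / tau0


def classify_mechanism(kq: float, threshold: float = DIFFUSION_LIMIT_KQ) -> str:
    """Label the quenching mechanism from the magnitude of Kq.

    ``static`` when Kq strictly exceeds the diffusion-controlled limit
    (the criterion is "significantly greater", so a value exactly at the
    threshold is still called ``dynamic``).
    """
    if kq < 0:
        raise ValueError(f"negative quenching rate constant {kq:g}")
    return "static" if kq > threshold else "dynamic"


def temperature_trend(results: Mapping[float, QuenchingResult] | Sequence[QuenchingResult]) -> str:
    """Corroborate the mechanism from the temperature dependence of Ksv.

    Strictly decreasing Ksv with temperature -> ``consistent_static``;
    strictly increasing -> ``consistent_dynamic``; anything else ->
    ``mixed``.
    """
    if isinstance(results, Mapping):
        items = sorted((float(t), r.ksv) for t, r in results.items())
    else:
        items = sorted((r.temperature, r.ksv) for r in results)
    if len(items) < 2:
        raise ValueError("temperature trend needs results at >= 2 temperatures")
    ksvs = [k for _, k in items]
    diffs = [b - a for a, b in zip(ksvs, ksvs[1:])]
    if all(d < 0 for d in diffs):
        return "consistent_static"
    if all(d > 0 for d in diffs):
        return "consistent_dynamic"
    return "mixed"
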