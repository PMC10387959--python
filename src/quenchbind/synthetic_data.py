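"""Forward simulators with known ground truth for every analysis stage.

The titration simulator inverts the two quenching models the analysis
fits — F(Q) = F0/(1 + Ksv*Q) for Stern-Volmer and F(Q) = F0/(1 + K*Q^n)
for the double-log binding model — on the eight-point concentration grid
0, 0.4, 0.8, 1.0, 1.6, 2.4, 3.2, 4.0 x 1e-5 mol/L used in the underlying
titration design, optionally attenuated by a synthetic inner-filter effect
and perturbed by multiplicative Gaussian noise (fluorescence error scales
with intensity; concentrations are assumed volumetrically exact and are
never perturbed).

The dissolution simulator plants a first-order cumulative release truth
C(t) = q_inf * (1 - exp(-k*t)) — a deliberately simple stand-in kinetic
model whose only job is to exercise the volume-corrected cumulative-release
arithmetic — and derives per-draw fractions A_i such that the release
formula recovers C(t_i) exactly in the noiseless case.

All simulators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cocrystal_phys import DissolutionSeries
from .titration_io import BASE_VALUES, TitrationPoint, TitrationSeries

__all__ = [
    "DEFAULT_Q_GRID",
    "TitrationScenario",
    "DissolutionScenario",
    "simulate_titration",
    "distort_inner_filter",
    "simulate_competition_pair",
    "simulate_dissolution",
    "recovery_medians",
]

#: quencher grid of the eight-point titration design, mol/L
DEFAULT_Q_GRID = (0.0, 0.4e-5, 0.8e-5, 1.0e-5, 1.6e-5, 2.4e-5, 3.2e-5, 4.0e-5)


@dataclass(frozen=True)
class TitrationScenario:
    """Ground truth for a simulated titration.

    ``model`` selects the forward model: ``stern_volmer`` uses ``true_ksv``;
    ``double_log`` uses ``true_k`` and ``true_n``.  ``noise_sd`` is the
    relative standard deviation of the multiplicative Gaussian intensity
    noise (default 1%).  ``ife`` optionally adds a synthetic inner-filter
    attenuation with per-concentration absorbance coefficients
    ``(eps_ex, eps_em)`` in L/mol.
    """

    model: str  # "stern_volmer" | "double_log"
    true_ksv: float | None = None  # L/mol
    true_k: float | None = None  # L/mol
    true_n: float | None = None
    f0: float = 1000.0  # arbitrary units
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    noise_sd: float = 0.01
    seed: int = 0
    temperature: float = 298.0  # K
    ife: tuple[float, float] | None = None  # (eps_ex, eps_em), L/mol
    ife_base: str = "ten"

    def __post_init__(self):
        if self.model not in ("stern_volmer", "double_log"):
            raise ValueError(f"invalid model tag {self.model!r}")
        if self.model == "stern_volmer" and not (self.true_ksv and self.true_ksv > 0):
            raise ValueError("stern_volmer model needs true_ksv > 0")
        if self.model == "double_log" and not (
            self.true_k and self.true_k > 0 and self.true_n and self.true_n > 0
        ):
            raise ValueError("double_log model needs true_k > 0 and true_n > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if 0.0 not in self.q_grid:
            raise ValueError("q_grid must include the zero-quencher reference")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass(frozen=True)
class DissolutionScenario:
    """Ground truth for a simulated dissolution run.

    First-order release C(t) = q_inf*(1 - exp(-rate_k*t)) sampled at
    ``times`` with ``v_sample`` mL withdrawn (and replaced) from ``v_medium``
    mL at each draw.
    """

    q_inf: float  # asymptotic released dose fraction, (0, 1]
    rate_k: float  # 1/min
    times: tuple[float, ...]  # min
    v_sample: float = 5.0  # mL
    v_medium: float = 100.0  # mL
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q_inf <= 1):
            raise ValueError("q_inf must lie in (0, 1]")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_titration(scenario: TitrationScenario) -> TitrationSeries:
    """Generate a titration series from a known quenching model.

    Noise is multiplicative Gaussian on every intensity (including the
    reference point); the same seed always yields the identical series.
    The optional inner-filter distortion is applied after the noise, so
    correcting it recovers the noisy — not the noiseless — intensities.
    """
    rng = np.random.default_rng(scenario.seed)
    qs = np.asarray(sorted(scenario.q_grid), dtype=float)
    if scenario.model == "stern_volmer":
        f = scenario.f0 / (1.0 + scenario.true_ksv * qs)
    else:
        f = scenario.f0 / (1.0 + scenario.true_k * qs**scenario.true_n)
    if scenario.noise_sd > 0:
        f = f * rng.normal(1.0, scenario.noise_sd, size=f.shape)
        f = np.maximum(f, 1e-12 * scenario.f0)  # intensities stay positive
    series = TitrationSeries(
        temperature=scenario.temperature,
        points=tuple(TitrationPoint(float(q), float(fi)) for q, fi in zip(qs, f)),
    )
    if scenario.ife is not None:
        eps_ex, eps_em = scenario.ife
        series = distort_inner_filter(series, eps_ex, eps_em, scenario.ife_base)
    return series


def distort_inner_filter(
    series: TitrationSeries,
    eps_ex: float,
    eps_em: float,
    base: str = "ten",
) -> TitrationSeries:
    """Attenuate a series by a synthetic inner-filter effect.

    Per point, sets a_ex = eps_ex*Q and a_em = eps_em*Q and multiplies the
    measured intensity by base**(-(a_ex + a_em)/2) — the exact inverse of
    the inner-filter correction with the same base.
    """
    if eps_ex < 0 or eps_em < 0:
        raise ValueError("absorbance coefficients must be non-negative")
    if base not in BASE_VALUES:
        raise ValueError(f"unknown base {base!r}")
    b = BASE_VALUES[base]
    new_points = []
    for p in series.points:
        a_ex = eps_ex * p.q_conc
        a_em = eps_em * p.q_conc
        new_points.append(
            TitrationPoint(
                q_conc=p.q_conc,
                f_measured=p.f_measured * b ** (-(a_ex + a_em) / 2.0),
                a_ex=a_ex,
                a_em=a_em,
            )
        )
    return replace(series, points=tuple(new_points), ife_base=None, flags=())


def simulate_competition_pair(
    k_free: float,
    displacement_site1: float,
    displacement_site2: float,
    marker_site1: str = "warfarin",
    marker_site2: str = "ibuprofen",
) -> dict[str, tuple[str, float]]:
    """Marker constants for a planted site-competition experiment.

    Each marker's constant is k_free * (1 - displacement); the marker with
    the larger displacement marks the planted binding site.  Returns a
    mapping suitable for ``binding.competition_site_assignment``.
    """
    from .binding import SITE_I, SITE_II

    if k_free <= 0:
        raise ValueError("k_free must be positive")
    for d in (displacement_site1, displacement_site2):
        if not (0.0 <= d < 1.0):
            raise ValueError(f"displacement {d:g} outside [0, 1)")
    return {
        marker_site1: (SITE_I, k_free * (1.0 - displacement_site1)),
        marker_site2: (SITE_II, k_free * (1.0 - displacement_site2)),
    }


def recovery_medians(
    true_k: float,
    true_n: float,
    n_replicates: int = 200,
    noise_sd: float = 0.01,
    master_seed: int = 42,
) -> tuple[float, float]:
    """Median (K, n) recovered by the double-log fit over seeded replicates.

    This is the package's standard parameter-recovery experiment: simulate
    ``n_replicates`` eight-point titrations from the double-log model with
    1% multiplicative intensity noise on the standard grid, fit each, and
    return the medians of the recovered binding constant and stoichiometry.
    Replicate seeds are spawned from ``master_seed`` (default 42, the
    experiment's defined seed).  The per-replicate intercept is an
    extrapolation over several decades of concentration, so individual
    recovered K values scatter widely; the median is the stable summary.
    """
    from .binding import fit_double_log

    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    ks, ns = [], []
    for s in seeds:
        series = simulate_titration(
            TitrationScenario(
                model="double_log",
                true_k=true_k,
                true_n=true_n,
                noise_sd=noise_sd,
                seed=int(s),
            )
        )
        res = fit_double_log(series)
        ks.append(res.k_b)
        ns.append(res.n_sites)
    return float(np.median(ks)), float(np.median(ns))


def simulate_dissolution(scenario: DissolutionScenario) -> DissolutionSeries:
    """Generate per-draw fractions whose cumulative release matches the truth.

    The per-draw fractions are constructed recursively,
    A_n = C(t_n) - (V1/V2) * sum_{i<n} A_i, so that the volume-corrected
    cumulative-release formula returns C(t_n) exactly when ``noise_sd`` is
    zero.  Optional seeded multiplicative noise perturbs the draws
    (truncated at zero).
    """
    rng = np.random.default_rng(scenario.seed)
    ratio = scenario.v_sample / scenario.v_medium
    fractions: list[float] = []
    prior_sum = 0.0
    for t in scenario.times:
        c_t = scenario.q_inf * (1.0 - math.exp(-scenario.rate_k * t))
        a = c_t - ratio * prior_sum
        if scenario.noise_sd > 0:
            a *= rng.normal(1.0, scenario.noise_sd)
        a = max(a, 0.0)
        fractions.append(a)
        prior_sum += a
    return DissolutionSeries(
        times=tuple(scenario.times),
        fractions=tuple(fractions),
        v_sample=scenario.v_sample,
        v_medium=scenario.v_medium,
    )
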