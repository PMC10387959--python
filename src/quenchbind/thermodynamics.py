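"""Van't Hoff thermodynamics of ligand-protein binding.

From binding constants at two (or more) temperatures the module computes

    dG(T) = -R * T * ln K(T)
    dH    =  R * ln(K2/K1) / (1/T1 - 1/T2)       (two temperatures)
    dS(T) = (dH - dG(T)) / T

with R = 8.314 J mol^-1 K^-1.  By construction dG = dH - T*dS holds exactly
at every temperature.  With more than two temperatures dH comes from an OLS
fit of ln K against 1/T (slope = -dH/R) — an extension beyond the two-point
design, flagged as such in the result.

The signs of dH and dS type the dominant non-covalent force: both positive
-> hydrophobic; both negative -> hydrogen bonding and van der Waals;
dS > 0 with dH <= 0 -> hydrophobic plus electrostatic; dS < 0 with
dH >= 0 -> hydrogen bonding and van der Waals.  Either quantity exactly
zero leaves the profile unclassified.

Published dH/dS tables are not always reproducible from the published K
values (e.g. a K that rises with temperature forces dH > 0 by the Van't
Hoff relation regardless of what the table prints).  When reference values
are supplied the module reports both, with a consistency warning, rather
than silently preferring either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "gibbs_from_k",
    "vant_hoff_enthalpy",
    "entropy_change",
    "classify_forces",
    "thermo_profile",
]

#: molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314

HYDROGEN_BOND = "hydrogen bond"
VAN_DER_WAALS = "van der Waals"
HYDROPHOBIC = "hydrophobic"
ELECTROSTATIC = "electrostatic"


@dataclass(frozen=True)
class ForceClassification:
    forces: frozenset[str]
    unclassified: bool = False


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic profile of binding over a set of temperatures.

    Internal units are SI (J/mol, J mol^-1 K^-1); reporting helpers convert
    dH and dG to kJ/mol.
    """

    delta_h: float  # J/mol
    delta_g_by_T: dict[float, float]  # T (K) -> J/mol
    delta_s_by_T: dict[float, float]  # T (K) -> J mol^-1 K^-1
    forces: frozenset[str]
    unclassified: bool
    gas_constant: float = GAS_CONSTANT
    warnings: tuple[str, ...] = ()


def gibbs_from_k(k: float, temperature: float) -> float:
    """Gibbs free energy of binding, dG = -R*T*ln K, in J/mol."""
    if k <= 0:
        raise ValueError(f"non-positive binding constant {k:g}")
    if temperature <= 0:
        raise ValueError(f"non-positive temperature {temperature:g} K")
    return -GAS_CONSTANT * temperature * math.log(k)


def vant_hoff_enthalpy(k1: float, t1: float, k2: float, t2: float) -> float:
    """Two-point Van't Hoff enthalpy, J/mol.

    dH = R * ln(k2/k1) / (1/t1 - 1/t2).
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("binding constants must be positive")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive")
    if t1 == t2:
        raise ValueError("Van't Hoff enthalpy needs two distinct temperatures")
    return GAS_CONSTANT * math.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)


def entropy_change(delta_h: float, delta_g: float, temperature: float) -> float:
    """Entropy change dS = (dH - dG)/T, in J mol^-1 K^-1."""
    if temperature <= 0:
        raise ValueError(f"non-positive temperature {temperature:g} K")
    return (delta_h - delta_g) / temperature


def classify_forces(delta_h: float, delta_s: float) -> ForceClassification:
    """Type the dominant interaction forces from the signs of dH and dS."""
    if delta_h == 0 or delta_s == 0:
        return ForceClassification(frozenset(), unclassified=True)
    if delta_h > 0 and delta_s > 0:
        return ForceClassification(frozenset({HYDROPHOBIC}))
    if delta_h < 0 and delta_s < 0:
        return ForceClassification(frozenset({HYDROGEN_BOND, VAN_DER_WAALS}))
    if delta_s > 0:  # dH < 0
        return ForceClassification(frozenset({HYDROPHOBIC, ELECTROSTATIC}))
    # dS < 0, dH > 0
    return ForceClassification(frozenset({HYDROGEN_BOND, VAN_DER_WAALS}))


def thermo_profile(
    k_by_temperature: Mapping[float, float],
    reference_delta_h: float | None = None,
    reference_delta_s: float | None = None,
) -> ThermoResult:
    """Full thermodynamic profile from binding constants per temperature.

    With exactly two temperatures dH is the two-point Van't Hoff value from
    the extreme pair; with more, an OLS fit of ln K vs 1/T (flagged as an
    extension beyond the two-temperature design).  dG and dS are computed
    per temperature; forces are classified from dH and the mean dS.

    ``reference_delta_h`` / ``reference_delta_s`` (SI units) are optional
    externally reported values: they are compared against the computed ones
    and any disagreement in sign or >25% in magnitude is reported as a
    warning; the computed values stay authoritative.
    """
    items = sorted((float(t), float(k)) for t, k in k_by_temperature.items())
    if len(items) < 2:
        raise ValueError("thermodynamic profile needs >= 2 temperatures")
    warnings: list[str] = []
    if len(items) == 2:
        (t1, k1), (t2, k2) = items
        delta_h = vant_hoff_enthalpy(k1, t1, k2, t2)
    else:
        inv_t = np.array([1.0 / t for t, _ in items])
        ln_k = np.array([math.log(k) for _, k in items])
        slope = float(np.polyfit(inv_t, ln_k, 1)[0])
        delta_h = -GAS_CONSTANT * slope
        warnings.append(
            "more than two temperatures: dH from OLS of ln K vs 1/T "
            "(beyond the two-point design)"
        )
    delta_g = {t: gibbs_from_k(k, t) for t, k in items}
    delta_s = {t: entropy_change(delta_h, delta_g[t], t) for t in delta_g}
    mean_ds = sum(delta_s.values()) / len(delta_s)
    cls = classify_forces(delta_h, mean_ds)

    if reference_delta_h is not None:
        if math.copysign(1, reference_delta_h) != math.copysign(1, delta_h) or (
            delta_h != 0
            and abs(reference_delta_h - delta_h) > 0.25 * abs(delta_h)
        ):
            warnings.append(
                f"supplied dH = {reference_delta_h / 1000:.4g} kJ/mol is "
                f"inconsistent with the Van't Hoff value "
                f"{delta_h / 1000:.4g} kJ/mol computed from the K(T) values; "
                "reporting both, computed value used for classification"
            )
    if reference_delta_s is not None:
        if math.copysign(1, reference_delta_s) != math.copysign(1, mean_ds) or (
            mean_ds != 0
            and abs(reference_delta_s - mean_ds) > 0.25 * abs(mean_ds)
        ):
            warnings.append(
                f"supplied dS = {reference_delta_s:.4g} J/mol/K is "
                f"inconsistent with the computed mean dS = {mean_ds:.4g} "
                "J/mol/K; reporting both, computed value used for "
                "classification"
            )
    return ThermoResult(
        delta_h=delta_h,
        delta_g_by_T=delta_g,
        delta_s_by_T=delta_s,
        forces=cls.forces,
        unclassified=cls.unclassified,
        warnings=tuple(warnings),
    )
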