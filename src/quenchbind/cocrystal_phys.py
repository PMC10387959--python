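"""Cocrystal physicochemistry: composition, dissolution, solubility, PXRD.

Four independent desk calculations that together establish whether an
API/coformer product is a genuine cocrystal with improved dissolution
behaviour:

* theoretical C/H/N mass fractions of a molecular formula, compared against
  combustion elemental analysis with a relative-error tolerance;
* cumulative dissolution release corrected for the analyte removed by
  earlier sampling draws:  Q_n = [A_n + (V1/V2) * sum_{i<n} A_i] * 100,
  where A_i is the dose fraction measured at draw i, V1 the sampled volume
  and V2 the medium volume (medium is replaced after each draw);
* apparent solubility enhancement as the product/parent ratio with a
  nearest-integer fold label;
* PXRD new-phase detection: product diffraction peaks with no parent peak
  within an angular tolerance indicate a new crystalline phase rather than
  a physical mixture.

Atomic weights come from the periodic table shipped with RDKit (IUPAC
standard weights: C 12.011, H 1.008, N 14.007, O 15.999).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from rdkit import Chem

__all__ = [
    "Formula",
    "CompositionReport",
    "DissolutionSeries",
    "ReleaseProfile",
    "PeakSet",
    "PxrdComparison",
    "mass_fractions",
    "composition_check",
    "cumulative_release",
    "solubility_ratio",
    "pxrd_new_phase",
]

_PT = Chem.GetPeriodicTable()
#: valid element symbols (H..Og)
_SYMBOLS = frozenset(_PT.GetElementSymbol(z) for z in range(1, 119))

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """A molecular formula as an element -> count map (counts >= 1)."""

    element_counts: Mapping[str, int]

    def __post_init__(self):
        if not self.element_counts:
            raise ValueError("empty formula")
        for sym, count in self.element_counts.items():
            if sym not in _SYMBOLS:
                raise ValueError(f"unknown element symbol {sym!r}")
            if not isinstance(count, int) or count < 1:
                raise ValueError(f"element {sym}: count must be a positive integer")

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a Hill-style formula such as ``C21H16N2O6``.

        No parentheses or isotopes; repeated symbols accumulate.
        """
        counts: dict[str, int] = {}
        pos = 0
        text = text.strip()
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            sym, digits = m.group(1), m.group(2)
            if sym not in _SYMBOLS:
                raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol from standard atomic weights."""
        return sum(
            _PT.GetAtomicWeight(sym) * n for sym, n in self.element_counts.items()
        )


@dataclass(frozen=True)
class CompositionReport:
    """Measured vs theoretical elemental mass fractions."""

    theoretical: dict[str, float]  # element -> mass %
    measured: dict[str, float]  # element -> mass %
    relative_errors: dict[str, float]  # element -> |meas-theo|/theo * 100
    tolerance: float  # %
    overall_pass: bool
    failing_elements: tuple[str, ...] = ()


@dataclass(frozen=True)
class DissolutionSeries:
    """Per-draw dose fractions from a volume-replacement dissolution run."""

    times: tuple[float, ...]  # min
    fractions: tuple[float, ...]  # A_i, dimensionless dose fraction per draw
    v_sample: float  # V1, mL withdrawn per draw
    v_medium: float  # V2, mL total medium

    def __post_init__(self):
        if len(self.times) == 0:
            raise ValueError("empty dissolution series")
        if len(self.times) != len(self.fractions):
            raise ValueError("times and fractions differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if any(a < 0 for a in self.fractions):
            raise ValueError("negative dose fraction")
        if not (0 <= self.v_sample <= self.v_medium) or self.v_medium <= 0:
            raise ValueError("require 0 <= v_sample <= v_medium, v_medium > 0")


@dataclass(frozen=True)
class ReleaseProfile:
    """Cumulative release Q_n (%) per sampling time."""

    times: tuple[float, ...]  # min
    q_percent: tuple[float, ...]


@dataclass(frozen=True)
class PeakSet:
    """A sorted list of diffraction peak positions in degrees 2-theta."""

    angles: tuple[float, ...]

    def __post_init__(self):
        if any(not (0.0 < a < 90.0) for a in self.angles):
            raise ValueError("peak angles must lie in (0, 90) degrees 2-theta")
        dedup: list[float] = []
        for a in sorted(self.angles):
            if not dedup or abs(a - dedup[-1]) > 1e-9:
                dedup.append(a)
        object.__setattr__(self, "angles", tuple(dedup))


@dataclass(frozen=True)
class PxrdComparison:
    new_peaks: PeakSet
    matched_peaks: PeakSet
    verdict: str  # "new_phase" | "superposition"
    tolerance: float  # degrees 2-theta


def mass_fractions(formula: Formula) -> dict[str, float]:
    """Theoretical mass percent per element; sums to 100 within 0.01."""
    total = formula.molar_mass
    return {
        sym: 100.0 * _PT.GetAtomicWeight(sym) * n / total
        for sym, n in formula.element_counts.items()
    }


def composition_check(
    formula: Formula,
    measured: Mapping[str, float],
    tolerance: float = 5.0,
) -> CompositionReport:
    """Compare measured elemental mass fractions against the formula.

    ``measured`` maps element symbols to measured mass percent; every
    measured element must occur in the formula.  Relative error is
    |measured - theoretical| / theoretical * 100, and the report passes when
    every error is within ``tolerance`` percent.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    theo = mass_fractions(formula)
    errors: dict[str, float] = {}
    failing: list[str] = []
    for sym, meas in measured.items():
        if sym not in theo:
            raise ValueError(f"measured element {sym!r} absent from formula")
        err = abs(meas - theo[sym]) / theo[sym] * 100.0
        errors[sym] = err
        if err > tolerance:
            failing.append(sym)
    return CompositionReport(
        theoretical={s: theo[s] for s in measured},
        measured=dict(measured),
        relative_errors=errors,
        tolerance=tolerance,
        overall_pass=not failing,
        failing_elements=tuple(failing),
    )


def cumulative_release(series: DissolutionSeries) -> ReleaseProfile:
    """Cumulative release with the sampled-volume correction.

    Q_n = [A_n + (V1/V2) * sum_{i<n} A_i] * 100.  With V1 = 0 the profile is
    just the raw fractions in percent; the first draw never needs a
    correction.
    """
    ratio = series.v_sample / series.v_medium
    q: list[float] = []
    prior_sum = 0.0
    for a in series.fractions:
        q.append((a + ratio * prior_sum) * 100.0)
        prior_sum += a
    return ReleaseProfile(times=series.times, q_percent=tuple(q))


def solubility_ratio(s_product: float, s_parent: float) -> tuple[float, int]:
    """Apparent-solubility enhancement: (ratio, nearest-integer fold label)."""
    if s_product <= 0 or s_parent <= 0:
        raise ValueError("solubilities must be positive")
    ratio = s_product / s_parent
    return ratio, round(ratio)


def pxrd_new_phase(
    product: PeakSet,
    parents: Sequence[PeakSet],
    tolerance: float = 0.2,
) -> PxrdComparison:
    """Detect a new crystalline phase from peak positions.

    A product peak with no parent peak within ``tolerance`` degrees 2-theta
    is new; the verdict is ``new_phase`` iff at least one new peak exists,
    else ``superposition`` (the product pattern is explainable as a physical
    mixture of the parents).
    """
    if not product.angles:
        raise ValueError("empty product peak set")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    parent_angles = [a for ps in parents for a in ps.angles]
    if not parent_angles:
        raise ValueError("no parent peaks given")
    new, matched = [], []
    for a in product.angles:
        if any(abs(a - b) <= tolerance for b in parent_angles):
            matched.append(a)
        else:
            new.append(a)
    return PxrdComparison(
        new_peaks=PeakSet(tuple(new)) if new else PeakSet(()),
        matched_peaks=PeakSet(tuple(matched)) if matched else PeakSet(()),
        verdict="new_phase" if new else "superposition",
        tolerance=tolerance,
    )
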