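"""Reading, validation and inner-filter correction of fluorescence titrations.

A titration series records the steady-state fluorescence of a fixed protein
solution (here human serum albumin, whose Trp-214 residue dominates the
intrinsic emission) as increasing amounts of a quencher — the drug or
pharmaceutical cocrystal — are added.  The zero-quencher point defines the
reference intensity ``F0``; every downstream analysis works on the ratio
``F0/F``, so intensities may be in any consistent arbitrary unit.

When the sample absorbs at the excitation or emission wavelength, the
measured intensity is attenuated (the *inner-filter effect*).  The
multiplicative correction applied here is

    F_corr = F_meas * base**((A_ex + A_em) / 2)

where ``A_ex`` and ``A_em`` are the absorbances at the excitation and the
maximum-emission wavelength.  The conventional correction uses base 10
(absorbances are decadic); a base-e variant is available as an explicit
option and the base in force is recorded on the series so reports can state
it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TitrationError",
    "TitrationPoint",
    "TitrationSeries",
    "correct_inner_filter",
    "correct_series",
    "read_titration_table",
    "validate_series",
    "series_to_json",
    "series_from_json",
    "write_titration_json",
    "read_titration_json",
    "BASE_VALUES",
    "Q_UNIT_FACTORS",
]


class TitrationError(ValueError):
    """Raised for malformed titration inputs."""


#: numeric value of each supported correction base
BASE_VALUES = {"ten": 10.0, "e": math.e}

#: multiplicative factor converting a declared concentration unit to mol/L
Q_UNIT_FACTORS = {
    "mol/L": 1.0,
    "mmol/L": 1e-3,
    "umol/L": 1e-6,
    "µmol/L": 1e-6,
    "1e-5 mol/L": 1e-5,
}


@dataclass(frozen=True)
class TitrationPoint:
    """One quencher level of a titration.

    Parameters
    ----------
    q_conc:
        Quencher concentration in mol/L (``0`` for the reference point).
    f_measured:
        Measured fluorescence intensity, arbitrary units; must be positive.
    a_ex, a_em:
        Optional absorbances at the excitation and maximum-emission
        wavelengths (dimensionless); both are required for the inner-filter
        correction.
    f_corrected:
        Inner-filter-corrected intensity, filled in by
        :func:`correct_series`.  Never smaller than ``f_measured``.
    """

    q_conc: float
    f_measured: float
    a_ex: float | None = None
    a_em: float | None = None
    f_corrected: float | None = None

    @property
    def intensity(self) -> float:
        """Corrected intensity when available, else the measured one."""
        return self.f_measured if self.f_corrected is None else self.f_corrected

    @property
    def has_absorbances(self) -> bool:
        return self.a_ex is not None and self.a_em is not None


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered fluorescence titration at a single temperature.

    Invariants (checked by :func:`validate_series`): at least three points,
    exactly one zero-quencher point, strictly increasing concentrations.
    ``f0`` is always taken from the (corrected) intensity of the
    zero-quencher point rather than supplied separately.
    """

    temperature: float  # K
    points: tuple[TitrationPoint, ...]
    excitation_wavelength: float | None = None  # nm
    ife_base: str | None = None  # correction base applied, if any
    flags: tuple[str, ...] = field(default=())

    @property
    def f0(self) -> float:
        for p in self.points:
            if p.q_conc == 0.0:
                return p.intensity
        raise TitrationError("no reference point (q_conc = 0) in series")

    @property
    def quenched_points(self) -> tuple[TitrationPoint, ...]:
        return tuple(p for p in self.points if p.q_conc > 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_conc": [p.q_conc for p in self.points],
                "f": [p.f_measured for p in self.points],
                "a_ex": [p.a_ex for p in self.points],
                "a_em": [p.a_em for p in self.points],
                "f_corrected": [p.f_corrected for p in self.points],
            }
        )


def correct_inner_filter(point: TitrationPoint, base: str = "ten") -> float:
    """Inner-filter-corrected intensity of a single point.

    Returns ``f_measured * base**((a_ex + a_em)/2)``.  When either
    absorbance is absent the measured intensity is returned unchanged (the
    caller is expected to flag the point as uncorrected, as
    :func:`correct_series` does).
    """
    if base not in BASE_VALUES:
        raise TitrationError(f"unknown correction base {base!r}; use 'ten' or 'e'")
    if not point.has_absorbances:
        return point.f_measured
    if point.a_ex < 0 or point.a_em < 0:
        raise TitrationError(
            f"negative absorbance at q = {point.q_conc:g} mol/L"
        )
    return point.f_measured * BASE_VALUES[base] ** ((point.a_ex + point.a_em) / 2.0)


def correct_series(series: TitrationSeries, base: str = "ten") -> TitrationSeries:
    """Apply the inner-filter correction to every point of a series.

    Points lacking absorbances keep their measured intensity and are flagged
    as uncorrected (one series-level flag when no point has absorbances at
    all).  The base used is recorded on the series.
    """
    new_points = []
    flags = []
    for p in series.points:
        if p.has_absorbances:
            new_points.append(replace(p, f_corrected=correct_inner_filter(p, base)))
        else:
            new_points.append(replace(p, f_corrected=p.f_measured))
            flags.append(f"uncorrected: no absorbances at q = {p.q_conc:g} mol/L")
    if len(flags) == len(series.points):
        flags = ["uncorrected: series has no absorbances; intensities used as-is"]
    return replace(series, points=tuple(new_points), ife_base=base, flags=tuple(flags))


def _build_series(
    rows: Iterable[tuple[float, float, float | None, float | None]],
    temperature: float,
    excitation_wavelength: float | None = None,
) -> TitrationSeries:
    pts = sorted(
        (TitrationPoint(q, f, a1, a2) for q, f, a1, a2 in rows),
        key=lambda p: p.q_conc,
    )
    series = TitrationSeries(
        temperature=temperature,
        points=tuple(pts),
        excitation_wavelength=excitation_wavelength,
    )
    problems = validate_series(series)
    if problems:
        raise TitrationError("; ".join(problems))
    return series


def read_titration_table(
    path,
    temperature: float,
    q_unit: str = "mol/L",
    excitation_wavelength: float | None = None,
) -> TitrationSeries:
    """Read a delimited titration table into a validated series.

    The file must have a header with columns ``q_conc`` and ``f``;
    ``a_ex``/``a_em`` are optional and must appear together.  Comment lines
    start with ``#``; comma and tab delimiters are auto-detected.
    Concentrations are converted from ``q_unit`` (one of ``mol/L``,
    ``mmol/L``, ``umol/L``, ``1e-5 mol/L``) to mol/L on load, and rows are
    sorted by concentration.
    """
    if q_unit not in Q_UNIT_FACTORS:
        raise TitrationError(
            f"unknown concentration unit {q_unit!r}; "
            f"supported: {sorted(Q_UNIT_FACTORS)}"
        )
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise TitrationError(f"cannot parse titration table {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("q_conc", "f"):
        if col not in df.columns:
            raise TitrationError(f"missing required column {col!r}")
    has_abs = "a_ex" in df.columns or "a_em" in df.columns
    if has_abs and not ("a_ex" in df.columns and "a_em" in df.columns):
        raise TitrationError("absorbance columns a_ex and a_em must appear together")
    cols = ["q_conc", "f"] + (["a_ex", "a_em"] if has_abs else [])
    try:
        numeric = df[cols].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TitrationError(f"non-numeric cell in titration table: {exc}") from exc

    factor = Q_UNIT_FACTORS[q_unit]
    rows = []
    for _, row in numeric.iterrows():
        if row[cols].isna().any():
            raise TitrationError("non-numeric or missing cell in titration table")
        a_ex = float(row["a_ex"]) if has_abs else None
        a_em = float(row["a_em"]) if has_abs else None
        rows.append((float(row["q_conc"]) * factor, float(row["f"]), a_ex, a_em))
    return _build_series(rows, temperature, excitation_wavelength)


def validate_series(series: TitrationSeries) -> list[str]:
    """Return a list of invariant violations; an empty list means valid."""
    problems: list[str] = []
    pts = series.points
    if len(pts) < 3:
        problems.append(f"fewer than 3 points ({len(pts)})")
    zero = [p for p in pts if p.q_conc == 0.0]
    if not zero:
        problems.append("no reference point (q_conc = 0)")
    elif len(zero) > 1:
        problems.append("more than one reference point (q_conc = 0)")
    for i, p in enumerate(pts):
        if p.q_conc < 0:
            problems.append(f"point {i}: negative concentration {p.q_conc:g}")
        if not p.f_measured > 0:
            problems.append(f"point {i}: non-positive intensity {p.f_measured:g}")
        if (p.a_ex is not None and p.a_ex < 0) or (p.a_em is not None and p.a_em < 0):
            problems.append(f"point {i}: negative absorbance")
        if p.f_corrected is not None and p.f_corrected < p.f_measured:
            problems.append(f"point {i}: corrected intensity below measured")
    qs = [p.q_conc for p in pts]
    for i in range(1, len(qs)):
        if qs[i] == qs[i - 1]:
            problems.append(f"duplicate concentration {qs[i]:g} mol/L")
        elif qs[i] < qs[i - 1]:
            problems.append("concentrations not sorted ascending")
    if series.temperature <= 0:
        problems.append(f"non-positive temperature {series.temperature:g} K")
    return problems


# --- JSON serialization ----------------------------------------------------

_SCHEMA = "quenchbind.titration-series/1"


def series_to_json(series: TitrationSeries) -> str:
    """Serialize a series with explicit units; round-trips bit-identically."""
    obj = {
        "schema": _SCHEMA,
        "temperature_K": series.temperature,
        "excitation_wavelength_nm": series.excitation_wavelength,
        "ife_base": series.ife_base,
        "flags": list(series.flags),
        "q_unit": "mol/L",
        "points": [
            {
                "q_conc": p.q_conc,
                "f_measured": p.f_measured,
                "a_ex": p.a_ex,
                "a_em": p.a_em,
                "f_corrected": p.f_corrected,
            }
            for p in series.points
        ],
    }
    return json.dumps(obj, indent=2)


def series_from_json(text: str) -> TitrationSeries:
    obj = json.loads(text)
    if obj.get("schema") != _SCHEMA:
        raise TitrationError(f"unexpected schema {obj.get('schema')!r}")
    pts = tuple(
        TitrationPoint(
            q_conc=p["q_conc"],
            f_measured=p["f_measured"],
            a_ex=p["a_ex"],
            a_em=p["a_em"],
            f_corrected=p["f_corrected"],
        )
        for p in obj["points"]
    )
    return TitrationSeries(
        temperature=obj["temperature_K"],
        points=pts,
        excitation_wavelength=obj["excitation_wavelength_nm"],
        ife_base=obj["ife_base"],
        flags=tuple(obj["flags"]),
    )


def write_titration_json(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(series_to_json(series))


def read_titration_json(path) -> TitrationSeries:
    with open(path) as fh:
        return series_from_json(fh.read())
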