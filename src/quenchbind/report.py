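"""Pipeline orchestration and report serialization.

``run_pipeline`` executes any subset of the analysis stages named in a
configuration mapping — titration fitting (inner-filter correction,
Stern-Volmer, double-log binding), thermodynamics, site-marker competition,
elemental composition, dissolution release, solubility ratio and PXRD
comparison — collects per-stage results and warnings into an
``AnalysisReport``, and never lets one failed stage abort the independent
ones.

The report serializes to a schema-versioned JSON document (round-trippable,
unknown top-level fields rejected on read) and to a human-readable text
layout.  Every numeric field name carries its unit.  Reports contain no
timestamp, so identical configurations produce byte-identical reports.

All randomness flows from a single top-level ``seed``; per-stage seeds are
derived deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

from . import __version__
from . import binding as _binding
from . import cocrystal_phys as _phys
from . import quenching as _quench
from . import thermodynamics as _thermo
from . import titration_io as _tio
from . import synthetic_data as _synth

__all__ = ["AnalysisReport", "run_pipeline", "write_report", "read_report"]

_SCHEMA = "quenchbind.report/1"

_KNOWN_STAGES = (
    "titrations",
    "thermo",
    "competition",
    "elemental",
    "dissolution",
    "solubility",
    "pxrd",
)


@dataclass
class AnalysisReport:
    """Aggregated per-stage results, warnings and provenance."""

    stages: dict[str, Any] = field(default_factory=dict)
    warnings: list[dict[str, str]] = field(default_factory=list)  # {stage, message}
    errors: list[dict[str, str]] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)
    schema: str = _SCHEMA

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append({"stage": stage, "message": message})

    def fail(self, stage: str, message: str) -> None:
        self.errors.append({"stage": stage, "message": message})

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema": self.schema,
            "stages": self.stages,
            "warnings": self.warnings,
            "errors": self.errors,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"quenchbind analysis report (schema {self.schema})", ""]
        for stage, payload in sorted(self.stages.items()):
            lines.append(f"== {stage} ==")
            lines.extend(_format_block(payload, indent=2))
            lines.append("")
        if self.warnings:
            lines.append("== WARNINGS ==")
            for w in self.warnings:
                lines.append(f"  [{w['stage']}] {w['message']}")
            lines.append("")
        if self.errors:
            lines.append("== ERRORS ==")
            for e in self.errors:
                lines.append(f"  [{e['stage']}] {e['message']}")
            lines.append("")
        lines.append(f"provenance: {json.dumps(self.provenance, sort_keys=True)}")
        return "\n".join(lines)


def _format_block(obj: Any, indent: int) -> list[str]:
    pad = " " * indent
    lines: list[str] = []
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            if isinstance(v, (Mapping, list)):
                lines.append(f"{pad}{k}:")
                lines.extend(_format_block(v, indent + 2))
            else:
                lines.append(f"{pad}{k}: {v}")
    elif isinstance(obj, list):
        for v in obj:
            if isinstance(v, (Mapping, list)):
                lines.append(f"{pad}-")
                lines.extend(_format_block(v, indent + 2))
            else:
                lines.append(f"{pad}- {v}")
    else:
        lines.append(f"{pad}{obj}")
    return lines


def _config_digest(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(seed: int, index: int) -> int:
    # deterministic per-stage derivation, kept below 2**31
    return (seed * 1_000_003 + index * 7919 + 17) % (2**31)


def _linear_fit_dict(fit: _quench.LinearFit) -> dict[str, Any]:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
    }


def _load_series(
    spec: Mapping[str, Any], seed: int, index: int
) -> _tio.TitrationSeries:
    temperature = float(spec.get("temperature", 298.0))
    if "input" in spec:
        return _tio.read_titration_table(
            spec["input"], temperature, q_unit=spec.get("q_unit", "mol/L")
        )
    if "synthetic" in spec:
        syn = dict(spec["synthetic"])
        syn.setdefault("temperature", temperature)
        syn.setdefault("seed", _stage_seed(seed, index))
        if "ife" in syn and syn["ife"] is not None:
            syn["ife"] = tuple(syn["ife"])
        if "q_grid" in syn:
            syn["q_grid"] = tuple(syn["q_grid"])
        return _synth.simulate_titration(_synth.TitrationScenario(**syn))
    raise ValueError("titration entry needs either 'input' or 'synthetic'")


def _run_titrations(config, report: AnalysisReport) -> dict[float, float]:
    """Per-temperature SV + binding fits; returns Kb per temperature."""
    base = config.get("ife_base", "ten")
    tau0 = float(config.get("tau0", _quench.DEFAULT_TAU0))
    intercept_mode = config.get("intercept_mode", "free")
    seed = int(config.get("seed", 0))
    out: dict[str, Any] = {}
    kb_by_t: dict[float, float] = {}
    sv_by_t: dict[float, _quench.QuenchingResult] = {}
    for i, spec in enumerate(config["titrations"]):
        label = f"titration@{spec.get('temperature', 298.0):g}K"
        try:
            series = _load_series(spec, seed, i)
            series = _tio.correct_series(series, base)
            for flag in series.flags:
                report.warn(label, flag)
            sv = _quench.fit_stern_volmer(series, intercept_mode, tau0)
            sv = _replace_mechanism(sv)
            for w in sv.warnings:
                report.warn(label, w)
            bind = _binding.fit_double_log(series)
            for w in bind.warnings:
                report.warn(label, w)
            affinity = _binding.affinity_class(bind.k_b)
            t = series.temperature
            kb_by_t[t] = bind.k_b
            sv_by_t[t] = sv
            out[f"{t:g}K"] = {
                "temperature_K": t,
                "ife_base": base,
                "quenching": {
                    "ksv_L_per_mol": sv.ksv,
                    "kq_L_per_mol_s": sv.kq,
                    "tau0_s": sv.tau0,
                    "mechanism": sv.mechanism,
                    "fit": _linear_fit_dict(sv.fit),
                },
                "binding": {
                    "log_k": bind.log_k,
                    "n_sites": bind.n_sites,
                    "k_b_L_per_mol": bind.k_b,
                    "affinity": affinity,
                    "fit": _linear_fit_dict(bind.fit),
                },
            }
        except (ValueError, _tio.TitrationError, OSError) as exc:
            report.fail(label, str(exc))
    if len(sv_by_t) >= 2:
        out["temperature_trend"] = _quench.temperature_trend(sv_by_t)
    if out:
        report.stages["titrations"] = out
    return kb_by_t


def _replace_mechanism(sv: _quench.QuenchingResult) -> _quench.QuenchingResult:
    from dataclasses import replace

    return replace(sv, mechanism=_quench.classify_mechanism(sv.kq))


def _run_thermo(config, report: AnalysisReport, kb_by_t: dict[float, float]) -> None:
    spec = config.get("thermo", {})
    k_by_t = {
        float(t): float(k) for t, k in spec.get("k_by_temperature", kb_by_t).items()
    }
    if len(k_by_t) < 2:
        report.fail("thermo", "needs binding constants at >= 2 temperatures")
        return
    ref_dh = spec.get("reference_delta_h_kj")
    ref_ds = spec.get("reference_delta_s")
    result = _thermo.thermo_profile(
        k_by_t,
        reference_delta_h=None if ref_dh is None else float(ref_dh) * 1000.0,
        reference_delta_s=None if ref_ds is None else float(ref_ds),
    )
    for w in result.warnings:
        report.warn("thermo", w)
    payload: dict[str, Any] = {
        "delta_h_kJ_per_mol": result.delta_h / 1000.0,
        "delta_g_kJ_per_mol": {f"{t:g}K": g / 1000.0 for t, g in result.delta_g_by_T.items()},
        "delta_s_J_per_mol_K": {f"{t:g}K": s for t, s in result.delta_s_by_T.items()},
        "forces": sorted(result.forces),
        "unclassified": result.unclassified,
        "gas_constant_J_per_mol_K": result.gas_constant,
    }
    if ref_dh is not None:
        payload["reference_delta_h_kJ_per_mol"] = float(ref_dh)
    if ref_ds is not None:
        payload["reference_delta_s_J_per_mol_K"] = float(ref_ds)
        # classification from the supplied (published) values, shown alongside
        cls = _thermo.classify_forces(
            float(ref_dh) * 1000.0 if ref_dh is not None else result.delta_h,
            float(ref_ds),
        )
        payload["forces_from_reference"] = sorted(cls.forces)
    report.stages["thermo"] = payload


def _run_competition(config, report: AnalysisReport) -> None:
    spec = config["competition"]
    markers = {
        name: (m["site"], float(m["k"])) for name, m in spec["markers"].items()
    }
    result = _binding.competition_site_assignment(
        float(spec["k_free"]), markers, float(spec.get("tie_margin", 0.02))
    )
    for w in result.warnings:
        report.warn("competition", w)
    report.stages["competition"] = {
        "k_free_L_per_mol": result.k_free,
        "marker_constants_L_per_mol": result.marker_constants,
        "relative_changes": result.relative_changes,
        "assigned_site": result.assigned_site,
        "tie_margin": result.tie_margin,
    }


def _run_elemental(config, report: AnalysisReport) -> None:
    spec = config["elemental"]
    formula = _phys.Formula.from_string(spec["formula"])
    check = _phys.composition_check(
        formula,
        {k: float(v) for k, v in spec["measured"].items()},
        float(spec.get("tolerance", 5.0)),
    )
    if not check.overall_pass:
        report.warn(
            "elemental",
            "relative error exceeds tolerance for: "
            + ", ".join(check.failing_elements),
        )
    report.stages["elemental"] = {
        "formula": spec["formula"],
        "molar_mass_g_per_mol": formula.molar_mass,
        "theoretical_mass_percent": check.theoretical,
        "measured_mass_percent": check.measured,
        "relative_error_percent": check.relative_errors,
        "tolerance_percent": check.tolerance,
        "overall_pass": check.overall_pass,
    }


def _run_dissolution(config, report: AnalysisReport) -> None:
    import pandas as pd

    spec = config["dissolution"]
    if "input" in spec:
        df = pd.read_csv(spec["input"], sep=None, engine="python", comment="#")
        times = tuple(float(t) for t in df["time"])
        fractions = tuple(float(a) for a in df["fraction"])
    else:
        times = tuple(float(t) for t in spec["times"])
        fractions = tuple(float(a) for a in spec["fractions"])
    series = _phys.DissolutionSeries(
        times=times,
        fractions=fractions,
        v_sample=float(spec.get("v_sample", 5.0)),
        v_medium=float(spec.get("v_medium", 100.0)),
    )
    profile = _phys.cumulative_release(series)
    report.stages["dissolution"] = {
        "times_min": list(profile.times),
        "cumulative_release_percent": list(profile.q_percent),
        "v_sample_mL": series.v_sample,
        "v_medium_mL": series.v_medium,
    }


def _run_solubility(config, report: AnalysisReport) -> None:
    spec = config["solubility"]
    ratio, fold = _phys.solubility_ratio(
        float(spec["s_product"]), float(spec["s_parent"])
    )
    report.stages["solubility"] = {
        "s_product_mol_per_L": float(spec["s_product"]),
        "s_parent_mol_per_L": float(spec["s_parent"]),
        "ratio": ratio,
        "fold_label": fold,
    }


def _read_peaks(source) -> _phys.PeakSet:
    if isinstance(source, (list, tuple)):
        return _phys.PeakSet(tuple(float(a) for a in source))
    import pandas as pd

    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    col = "two_theta" if "two_theta" in df.columns else df.columns[0]
    return _phys.PeakSet(tuple(float(a) for a in df[col]))


def _run_pxrd(config, report: AnalysisReport) -> None:
    spec = config["pxrd"]
    product = _read_peaks(spec["product"])
    parents = [_read_peaks(p) for p in spec["parents"]]
    cmp = _phys.pxrd_new_phase(product, parents, float(spec.get("tolerance", 0.2)))
    report.stages["pxrd"] = {
        "verdict": cmp.verdict,
        "new_peaks_2theta_deg": list(cmp.new_peaks.angles),
        "matched_peaks_2theta_deg": list(cmp.matched_peaks.angles),
        "tolerance_2theta_deg": cmp.tolerance,
    }


def run_pipeline(config: Mapping[str, Any]) -> AnalysisReport:
    """Run every stage named in ``config`` and aggregate the results.

    Stages are independent: a failure is recorded under ``errors`` and the
    remaining stages still run.  The thermodynamics stage consumes the
    per-temperature binding constants of the titration stage unless the
    config supplies ``thermo.k_by_temperature`` explicitly.  Raises when the
    config requests no stage at all.
    """
    requested = [s for s in _KNOWN_STAGES if s in config]
    if not requested:
        raise ValueError("no stages requested")
    unknown = set(config) - set(_KNOWN_STAGES) - {
        "seed", "ife_base", "tau0", "intercept_mode"
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    report = AnalysisReport(
        provenance={
            "software": f"quenchbind {__version__}",
            "config_digest": _config_digest(config),
            "seed": int(config.get("seed", 0)),
            "ife_base": config.get("ife_base", "ten"),
        }
    )
    kb_by_t: dict[float, float] = {}
    if "titrations" in config:
        kb_by_t = _run_titrations(config, report)
    runners = {
        "thermo": lambda: _run_thermo(config, report, kb_by_t),
        "competition": lambda: _run_competition(config, report),
        "elemental": lambda: _run_elemental(config, report),
        "dissolution": lambda: _run_dissolution(config, report),
        "solubility": lambda: _run_solubility(config, report),
        "pxrd": lambda: _run_pxrd(config, report),
    }
    for stage in requested:
        if stage == "titrations":
            continue
        if stage == "thermo" and "thermo" not in config and len(kb_by_t) < 2:
            continue
        try:
            runners[stage]()
        except (ValueError, KeyError, OSError) as exc:
            report.fail(stage, str(exc))
    # thermodynamics falls out of a two-temperature titration run even
    # without an explicit thermo section
    if "thermo" not in config and len(kb_by_t) >= 2:
        try:
            _run_thermo({"thermo": {}}, report, kb_by_t)
        except ValueError as exc:
            report.fail("thermo", str(exc))
    return report


def write_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Write a report as schema-stable JSON or as readable text."""
    if format not in ("json", "text"):
        raise ValueError(f"unknown report format {format!r}")
    text = report.to_json() if format == "json" else report.to_text()
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_report(path) -> AnalysisReport:
    """Read a JSON report back, rejecting unknown fields and schemas."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported report schema {obj.get('schema')!r}")
    known = {"schema", "stages", "warnings", "errors", "provenance"}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown report fields: {sorted(unknown)}")
    return AnalysisReport(
        stages=obj["stages"],
        warnings=obj["warnings"],
        errors=obj["errors"],
        provenance=obj["provenance"],
        schema=obj["schema"],
    )
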