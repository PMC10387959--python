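"""Published reference values for the apigenin-nicotinamide / HSA system.

These constants are the reported measurements for the apigenin (AP) -
nicotinamide (Nico) pharmaceutical cocrystal binding to human serum albumin
that the worked examples and the validation suite use as inputs and ground
truths.  They are data, not code defaults: analyses never fall back to them
silently.

Known internal inconsistencies of the published tables, preserved here so
the analysis layer can flag them rather than reproduce them:

* the reported binding-constant column disagrees with its own reported
  double-log intercepts by roughly a factor of 10 (10**7.66 = 4.57e7, yet
  Kb is given as 4.57e6); the intercept-vs-Kb check in ``binding`` warns
  about this;
* the reported dH/dS are not reproducible from the reported K(T) via the
  Van't Hoff relation (K rising with temperature forces dH > 0, but the
  table prints dH < 0); ``thermodynamics.thermo_profile`` warns when handed
  both;
* the solubility table labels its low-temperature row 278 K while the
  surrounding text describes measurements at 298 K; the preset stores 298 K.
"""

from __future__ import annotations

from .binding import SITE_I, SITE_II

# --- molecular formulas ------------------------------------------------------

APIGENIN_FORMULA = "C15H10O5"
NICOTINAMIDE_FORMULA = "C6H6N2O"
COCRYSTAL_FORMULA = "C21H16N2O6"  # 1:1 AP:Nico

#: measured combustion elemental analysis, mass % per element
ELEMENTAL_MEASURED = {
    "AP": {"C": 64.68, "H": 3.85},
    "Nico": {"C": 58.50, "H": 5.02, "N": 22.94},
    "AP-Nico": {"C": 64.47, "H": 3.98, "N": 6.93},
}

# --- fluorescence titration design ------------------------------------------

#: eight-point quencher grid, mol/L
Q_GRID = (0.0, 0.4e-5, 0.8e-5, 1.0e-5, 1.6e-5, 2.4e-5, 3.2e-5, 4.0e-5)

#: unquenched fluorophore lifetime used throughout, s
TAU0 = 1e-8

#: reported Stern-Volmer constants, L/mol, per system and temperature (K)
KSV = {
    "AP": {298.0: 0.27e5, 310.0: 0.13e5},
    "AP-Nico": {298.0: 5.54e5, 310.0: 3.82e5},
}

#: reported double-log binding fits: intercept (log10 K), slope n and the
#: reported Kb column (L/mol).  The AP-Nico 310 K intercept is unusable in
#: the source (a typographic defect drops its operator), so only the
#: reported Kb is carried for that condition.
BINDING = {
    "AP": {
        298.0: {"log_k": 6.83, "n": 1.36, "k_b_reported": 0.67e6},
        310.0: {"log_k": 7.38, "n": 1.46, "k_b_reported": 2.39e6},
    },
    "AP-Nico": {
        298.0: {"log_k": 7.66, "n": 1.48, "k_b_reported": 4.57e6},
        310.0: {"log_k": None, "n": 1.93, "k_b_reported": 5.01e6},
    },
}

#: site-marker competition constants at 298 K, L/mol
COMPETITION = {
    "AP": {"warfarin": (SITE_I, 0.57e5), "ibuprofen": (SITE_II, 1.89e5)},
    "AP-Nico": {"warfarin": (SITE_I, 1.05e5), "ibuprofen": (SITE_II, 1.73e5)},
}

#: reported thermodynamic parameters (dH, dG in kJ/mol; dS in J/mol/K)
THERMO_REPORTED = {
    "AP": {
        "delta_h_kj": -47.34,
        "delta_s": -59.91,
        "delta_g_kj": {298.0: -33.28, 310.0: -34.34},
    },
    "AP-Nico": {
        "delta_h_kj": -14.45,
        "delta_s": -21.36,
        "delta_g_kj": {298.0: -38.47, 310.0: -36.56},
    },
}

#: apparent solubilities after 72 h, mol/L: T -> (parent AP, AP-Nico).
#: The low-temperature row is stored as 298 K (see module docstring).
SOLUBILITY = {
    298.0: (0.23e-5, 0.57e-5),
    310.0: (0.28e-5, 0.81e-5),
}

SOLUBILITY_TEMPERATURE_NOTE = (
    "the published solubility table labels its low-temperature row 278 K "
    "while the accompanying text describes 298 K; this preset stores 298 K"
)

#: characteristic PXRD peaks, degrees 2-theta
PXRD_PEAKS = {
    "AP": (11.08, 14.08, 15.86),
    "Nico": (14.92, 25.84, 27.71),
    "AP-Nico-new": (7.31, 10.36, 20.68),
}

#: cumulative dissolution reached after 240 min at pH 4.5, dose fraction
DISSOLUTION_240MIN = {"AP": 0.43, "AP-Nico": 0.71}

#: dissolution sampling schedule, min
DISSOLUTION_TIMES = (5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180, 240)
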