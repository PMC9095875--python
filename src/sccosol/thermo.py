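"""Derived thermodynamic quantities and qualitative solubility diagnostics.

The 1/T slopes of the density-based correlations carry enthalpies:

* Bartle slope G1  ->  vaporization enthalpy  dHvap = -G1 * R
* Chrastil slope E1 (or reformulated-Chrastil F1)  ->  total heat
  dHtotal = -E1 * R, the sum of vaporization and solvation contributions
* solvation enthalpy = total - vaporization (negative: exothermic)

Also here: crossover-pressure detection (the pressure where solubility
isotherms intersect, separating the density-dominated from the
sublimation-pressure-dominated regime) and the Mendez-Santiago--Teja
self-consistency transform, under which mutually consistent data at all
temperatures collapse onto one straight line in the density coordinate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dataset import SolubilityDataset, SubstanceConstants
from .fitting import FitConfig, FitResult, fit_model

__all__ = [
    "EnthalpyReport",
    "CrossoverResult",
    "vaporization_enthalpy",
    "total_enthalpy",
    "solvation_enthalpy",
    "enthalpy_report",
    "crossover_pressure",
    "mt_consistency_transform",
]

R_DEFAULT = 8.314  # J/(mol K)


def vaporization_enthalpy(G1: float, R: float = R_DEFAULT) -> float:
    """Vaporization enthalpy in kJ/mol from the Bartle 1/T slope: -G1*R/1000."""
    return -G1 * R / 1000.0


def total_enthalpy(slope: float, R: float = R_DEFAULT) -> float:
    """Total heat in kJ/mol from a Chrastil-type 1/T slope (E1 or F1):
    -slope*R/1000 (positive for the usual negative slopes)."""
    return -slope * R / 1000.0


def solvation_enthalpy(total: float, vaporization: float) -> float:
    """Solvation enthalpy = total - vaporization, in kJ/mol (negative =
    exothermic)."""
    return total - vaporization


@dataclass(frozen=True)
class EnthalpyReport:
    total_kJ_mol: float
    vaporization_kJ_mol: float
    solvation_kJ_mol: float
    source_pair: tuple[str, str]


def enthalpy_report(
    total_fit: FitResult, bartle_fit: FitResult, R: float = R_DEFAULT
) -> EnthalpyReport:
    """Combine a Chrastil-type fit (slope = last parameter, E1 or F1) with a
    Bartle fit (slope G1) into the enthalpy triple."""
    total_id = total_fit.parameter_set.model_id
    if total_id not in ("chrastil", "r_chrastil"):
        raise ValueError(f"total-heat fit must be chrastil/r_chrastil, got {total_id}")
    if bartle_fit.parameter_set.model_id != "bartle":
        raise ValueError("vaporization fit must be the bartle model")
    slope = total_fit.parameter_set.values[2]
    G1 = bartle_fit.parameter_set.values[1]
    total = total_enthalpy(slope, R)
    vap = vaporization_enthalpy(G1, R)
    return EnthalpyReport(
        total_kJ_mol=total,
        vaporization_kJ_mol=vap,
        solvation_kJ_mol=solvation_enthalpy(total, vap),
        source_pair=(total_id, "bartle"),
    )


# ---------------------------------------------------------------------------
# Crossover pressure


@dataclass(frozen=True)
class CrossoverResult:
    """Pairwise isotherm crossings of ln(y2) vs P.

    ``crossings`` maps (T_low, T_high) to the interpolated crossing pressure;
    pairs whose solubility ordering never flips are absent. ``estimate`` is
    the mean crossing; ``bracket`` the tightest grid interval containing all
    crossings. ``found`` is False when no pair flips.
    """

    crossings: dict[tuple[float, float], float]
    estimate: float | None
    bracket: tuple[float, float] | None

    @property
    def found(self) -> bool:
        return bool(self.crossings)


def _pair_crossing(P, ly_a, ly_b):
    """Crossing pressure of two piecewise-linear curves ln(y) vs P, or None."""
    d = ly_a - ly_b
    for i in range(len(P) - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            return float(P[i])
        if d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            return float(P[i] + frac * (P[i + 1] - P[i]))
    if d[-1] == 0.0:
        return float(P[-1])
    return None


def crossover_pressure(dataset: SolubilityDataset) -> CrossoverResult:
    """Locate the crossover pressure from pairwise isotherm intersections.

    For every pair of isotherms sharing the pressure grid, interpolates
    ln(y2) linearly in P and finds where the two interpolants cross. A pair
    with no ordering flip contributes nothing; if no pair flips the result
    has ``found == False`` rather than raising.
    """
    isos = dataset.isotherms()
    temps = sorted(isos)
    if len(temps) < 2:
        raise ValueError("crossover detection needs at least two isotherms")
    crossings: dict[tuple[float, float], float] = {}
    grid_points: list[float] = []
    for ta, tb in itertools.combinations(temps, 2):
        A, B = isos[ta], isos[tb]
        Pa = np.array([r.pressure for r in A.records])
        Pb = np.array([r.pressure for r in B.records])
        common = np.intersect1d(Pa, Pb)
        if common.size < 2:
            continue
        ly_a = np.log([r.mole_fraction for r in A.records if r.pressure in common])
        ly_b = np.log([r.mole_fraction for r in B.records if r.pressure in common])
        pc = _pair_crossing(common, ly_a, ly_b)
        if pc is not None:
            crossings[(ta, tb)] = pc
            # bracketing grid interval for this crossing
            below = common[common <= pc]
            above = common[common >= pc]
            if below.size and above.size:
                grid_points.append(float(below.max()))
                grid_points.append(float(above.min()))
    if not crossings:
        return CrossoverResult({}, None, None)
    vals = list(crossings.values())
    return CrossoverResult(
        crossings=crossings,
        estimate=float(np.mean(vals)),
        bracket=(min(grid_points), max(grid_points)),
    )


# ---------------------------------------------------------------------------
# MT self-consistency


def mt_consistency_transform(
    dataset: SolubilityDataset, H2: float
) -> list[tuple[float, float]]:
    """Coordinates of the MT self-consistency plot:
    ``(rho1, T ln(y2 P) - H2 T)`` per record.

    With the fitted (H0, H1, H2), the scatter of these points about the line
    ``H0 + H1 rho1`` equals the MT fit residuals in transformed space;
    temperature-independent scatter indicates self-consistent data.
    """
    out = []
    for r in dataset.records:
        val = r.temperature * np.log(r.mole_fraction * r.pressure) - H2 * r.temperature
        out.append((r.co2_density, float(val)))
    return out
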