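"""The eight solubility correlations as pure prediction functions
``y2 = f(T, P, rho1; theta)``.

Three model families are covered:

* a solid-liquid-equilibrium model in which supercritical CO2 is treated as
  an expanded liquid: the mole-fraction solubility is the solid/liquid
  fugacity ratio of the solute divided by its infinite-dilution activity
  coefficient, the latter from regular solution theory with density-scaled
  solubility parameters (``new_model``);
* reduced-variable / empirical correlations from the recent literature
  (``alwi_garlapati``, ``sodeifian``, ``reddy_garlapati``);
* the conventional density-based models (``chrastil``, ``r_chrastil``,
  ``bartle``, ``mt``) whose 1/T slopes carry enthalpic meaning.

All predictors take temperature in K, pressure in MPa and CO2 density in
kg/m3 and convert internally to each model's native convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import SubstanceConstants

__all__ = [
    "ModelDefinition",
    "ParameterSet",
    "MODELS",
    "get_model",
    "fugacity_ratio",
    "gamma_infinity",
    "predict_new_model",
    "predict_alwi_garlapati",
    "predict_sodeifian",
    "predict_reddy_garlapati",
    "predict_chrastil",
    "predict_r_chrastil",
    "predict_bartle",
    "predict_mt",
]

logger = logging.getLogger("sccosol")

EXP_CLIP = 700.0  # exp argument clip; optimizers may probe absurd regions

_clip_warned = False


def _exp(x):
    """exp with overflow guard: arguments clipped to +-700, warned once."""
    global _clip_warned
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > EXP_CLIP):
        if not _clip_warned:
            logger.warning(
                "exp argument clipped to +-%g (warned once per session)", EXP_CLIP
            )
            _clip_warned = True
        x = np.clip(x, -EXP_CLIP, EXP_CLIP)
    return np.exp(x)


@dataclass(frozen=True)
class ModelDefinition:
    """A named correlation: parameter list, bounds, and a prediction contract."""

    model_id: str
    parameter_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    predict: Callable  # (T, P, rho1, theta, constants) -> y2
    requires: frozenset = frozenset({"T", "rho1"})
    log_sample: tuple[bool, ...] | None = None  # LHS on log10 scale per param

    @property
    def parameter_count(self) -> int:
        return len(self.parameter_names)

    def __call__(self, T, P, rho1, theta, constants: SubstanceConstants):
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.parameter_count:
            raise ValueError(
                f"{self.model_id} expects {self.parameter_count} parameters, "
                f"got {theta.shape[-1]}"
            )
        return self.predict(T, P, rho1, theta, constants)


@dataclass(frozen=True)
class ParameterSet:
    """Fitted parameter values for one model, global or per-isotherm."""

    model_id: str
    values: tuple[float, ...]
    scope: str = "global"  # "global" | "per_isotherm"
    isotherm_temperature: float | None = None

    def __post_init__(self) -> None:
        model = get_model(self.model_id)
        if len(self.values) != model.parameter_count:
            raise ValueError(
                f"{self.model_id} takes {model.parameter_count} parameters, "
                f"got {len(self.values)}"
            )
        if self.scope == "per_isotherm" and self.isotherm_temperature is None:
            raise ValueError("per_isotherm parameter set needs isotherm_temperature")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(get_model(self.model_id).parameter_names, self.values))


# ---------------------------------------------------------------------------
# Solid-liquid equilibrium components


def fugacity_ratio(
    T: float,
    Tm: float,
    dHm: float | None = None,
    dCp: float = 0.0,
    R: float = 8.314,
    melting_term: str = "printed",
):
    """Solid/liquid fugacity ratio f2S/f2L of the solute at temperature T.

    With a known melting enthalpy ``dHm`` (J/mol) the full constant-heat-
    capacity expression is used:

        ln(f2S/f2L) = dHm/(R T) (T/Tm - 1)
                      - dCp/R [ln(T/Tm) - Tm (1/Tm - 1/T)]

    When ``dHm`` is None (e.g. sodium-containing solutes for which group
    contribution estimates fail) the melting-enthalpy term is replaced by the
    empirical constant-entropy substitution with coefficient 6.54. The
    substitution appears in the literature in two sign variants, selected by
    ``melting_term``: "printed" uses 6.54 (1 - T/Tm), "textual" uses
    6.54 (1 - Tm/T). At T = Tm every variant gives a ratio of exactly 1.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or Tm <= 0:
        raise ValueError("temperatures must be > 0 K")
    if dHm is None:
        if melting_term == "printed":
            melt = 6.54 * (1.0 - T / Tm)
        elif melting_term == "textual":
            melt = 6.54 * (1.0 - Tm / T)
        else:
            raise ValueError(f"unknown melting_term variant: {melting_term!r}")
    else:
        melt = dHm / (R * T) * (T / Tm - 1.0)
    cp_term = (dCp / R) * (np.log(T / Tm) - Tm * (1.0 / Tm - 1.0 / T))
    return _exp(melt - cp_term)


def gamma_infinity(T, rho1, v2: float, a11, a22, R: float = 8.314):
    """Infinite-dilution activity coefficient of the solute from regular
    solution theory with density-scaled solubility parameters.

    gamma2_inf = exp[(a22 + a11 v2 rho1 - 2 sqrt(a11 a22) (v2 rho1)^0.5)
                     / (R T)]

    ``a11`` and ``a22`` (>= 0) are solvent-solvent and solute-solute
    interaction potentials; ``v2`` is the solute molar volume in m3/mol and
    ``rho1`` the CO2 density in kg/m3. Only positivity of the result is
    guaranteed by contract.
    """
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(T <= 0) or np.any(rho1 <= 0) or v2 <= 0:
        raise ValueError("T, rho1 and v2 must be > 0")
    if np.any(np.asarray(a11) < 0) or np.any(np.asarray(a22) < 0):
        raise ValueError("a11 and a22 must be >= 0")
    s = v2 * rho1
    exponent = (a22 + a11 * s - 2.0 * np.sqrt(a11 * a22) * np.sqrt(s)) / (R * T)
    return _exp(exponent)


# ---------------------------------------------------------------------------
# Predictors.  Signature: (T, P, rho1, theta, constants) -> y2


def predict_new_model(T, P, rho1, theta, constants: SubstanceConstants,
                      melting_term: str = "printed"):
    """Expanded-liquid solubility: fugacity ratio over activity coefficient.

    theta = (dCp, a11, a22): heat-capacity difference of the solute between
    solid and expanded-liquid phases (J/(mol K)) and the two interaction
    potentials of the regular-solution activity model.
    """
    dCp, a11, a22 = theta
    f_ratio = fugacity_ratio(
        T,
        constants.solute_melting_temperature,
        dHm=None,
        dCp=dCp,
        R=constants.gas_constant,
        melting_term=melting_term,
    )
    gamma = gamma_infinity(
        T, rho1, constants.solute_molar_volume, a11, a22, R=constants.gas_constant
    )
    return f_ratio / gamma


def predict_new_model_textual(T, P, rho1, theta, constants: SubstanceConstants):
    """`new_model` with the textual sign variant of the 6.54 melting term."""
    return predict_new_model(T, P, rho1, theta, constants, melting_term="textual")


def predict_alwi_garlapati(T, P, rho1, theta, constants: SubstanceConstants):
    """Reduced-density model: y2 = exp(A0 + A1/Tr + A2*rho_r) / (rho_r Tr)."""
    A0, A1, A2 = theta
    if constants.solvent_Tc <= 0 or constants.solvent_rhoc <= 0:
        raise ValueError("solvent critical constants must be positive")
    Tr = np.asarray(T, dtype=float) / constants.solvent_Tc
    rho_r = np.asarray(rho1, dtype=float) / constants.solvent_rhoc
    return _exp(A0 + A1 / Tr + A2 * rho_r) / (rho_r * Tr)


def predict_sodeifian(T, P, rho1, theta, constants: SubstanceConstants):
    """Six-parameter empirical model, nonlinear in (T, P, rho1):

    ln y2 = B0 + B1 P^2/T + B2 ln(rho1 T) + B3 rho1 ln(rho1)
            + B4 P ln(T) + B5 ln(rho1)/T

    with T in K, P in MPa, rho1 in kg/m3.
    """
    B0, B1, B2, B3, B4, B5 = theta
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    ln_rho = np.log(rho1)
    arg = (
        B0
        + B1 * P**2 / T
        + B2 * np.log(rho1 * T)
        + B3 * rho1 * ln_rho
        + B4 * P * np.log(T)
        + B5 * ln_rho / T
    )
    return _exp(arg)


def predict_reddy_garlapati(T, P, rho1, theta, constants: SubstanceConstants):
    """Dimensionless reduced-variable model, quadratic in Pr within each of
    two Tr blocks:

        y2 = (D0 + D1 Pr + D2 Pr^2) Tr^2 + (D3 + D4 Pr + D5 Pr^2)

    The raw polynomial value is returned; it can go negative for
    pathological parameters, which the fit objective penalises naturally.
    """
    D0, D1, D2, D3, D4, D5 = theta
    Tr = np.asarray(T, dtype=float) / constants.solvent_Tc
    Pr = np.asarray(P, dtype=float) / constants.solvent_Pc
    return (D0 + D1 * Pr + D2 * Pr**2) * Tr**2 + (D3 + D4 * Pr + D5 * Pr**2)


def predict_chrastil(T, P, rho1, theta, constants: SubstanceConstants):
    """Chrastil solvate-complex model in its mole-fraction form.

    With x = rho1^(kappa-1) exp(E0 + E1/T), returns y2 = x / (1 + x), which
    keeps predictions in (0, 1). kappa is the apparent association number
    (solvent molecules per solvato-complex); E1 is a 1/T slope whose value
    times -R is the total (reaction + vaporization) heat.
    """
    kappa, E0, E1 = theta
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    x = _exp((kappa - 1.0) * np.log(rho1) + E0 + E1 / T)
    return x / (1.0 + x)


def predict_r_chrastil(T, P, rho1, theta, constants: SubstanceConstants):
    """Dimensionally consistent (reformulated) Chrastil model:

        y2 = (R T rho1 / (M_scf f0))^(kappa'-1) exp(F0 + F1/T)

    The base of the power is made dimensionless with SI units: R in
    J/(mol K), rho1 in kg/m3, M_scf in kg/mol and the standard-state
    fugacity f0 in Pa (constants store it in MPa).
    """
    kappa_p, F0, F1 = theta
    if constants.rchrastil_f0 <= 0:
        raise ValueError("standard-state fugacity must be positive")
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    M_kg = constants.solvent_molar_mass / 1000.0
    f0_Pa = constants.rchrastil_f0 * 1.0e6
    base = constants.gas_constant * T * rho1 / (M_kg * f0_Pa)
    return _exp((kappa_p - 1.0) * np.log(base) + F0 + F1 / T)


def predict_bartle(T, P, rho1, theta, constants: SubstanceConstants):
    """Bartle et al. model:

        ln(y2 P / Pref) = G0 + G1/T + G2 (rho1 - rhoref)

    P and Pref in MPa, rho in kg/m3. -G1*R is the solute vaporization
    enthalpy.
    """
    G0, G1, G2 = theta
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValueError("pressure must be > 0")
    rho1 = np.asarray(rho1, dtype=float)
    return (
        constants.bartle_Pref / P
        * _exp(G0 + G1 / T + G2 * (rho1 - constants.bartle_rhoref))
    )


def predict_mt(T, P, rho1, theta, constants: SubstanceConstants):
    """Mendez-Santiago--Teja model, inverted to mole-fraction form:

        T ln(y2 P) - H2 T = H0 + H1 rho1
        =>  y2 = exp((H0 + H1 rho1)/T + H2) / P

    P in MPa. The linearity of T ln(y2 P) - H2 T in rho1 across all
    isotherms is the standard self-consistency check for solubility data.
    """
    H0, H1, H2 = theta
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0):
        raise ValueError("T and P must be > 0")
    rho1 = np.asarray(rho1, dtype=float)
    return _exp((H0 + H1 * rho1) / T + H2) / P


# ---------------------------------------------------------------------------
# Registry

_BIG = 1.0e3

MODELS: dict[str, ModelDefinition] = {
    m.model_id: m
    for m in [
        ModelDefinition(
            "new_model",
            ("dCp", "a11", "a22"),
            bounds=((-1.0e6, 1.0e6), (0.0, 1.0e9), (0.0, 1.0e9)),
            predict=predict_new_model,
            requires=frozenset({"T", "rho1", "constants"}),
            log_sample=(False, True, True),
        ),
        ModelDefinition(
            "alwi_garlapati",
            ("A0", "A1", "A2"),
            bounds=((-100.0, 100.0), (-200.0, 200.0), (-50.0, 50.0)),
            predict=predict_alwi_garlapati,
            requires=frozenset({"T", "rho1", "constants"}),
        ),
        ModelDefinition(
            "sodeifian",
            ("B0", "B1", "B2", "B3", "B4", "B5"),
            bounds=(
                (-100.0, 100.0),
                (-1.0, 1.0),
                (-50.0, 50.0),
                (-0.1, 0.1),
                (-1.0, 1.0),
                (-50000.0, 50000.0),
            ),
            predict=predict_sodeifian,
            requires=frozenset({"T", "P", "rho1"}),
        ),
        ModelDefinition(
            "reddy_garlapati",
            ("D0", "D1", "D2", "D3", "D4", "D5"),
            bounds=tuple(((-1.0e-2, 1.0e-2),) * 6),
            predict=predict_reddy_garlapati,
            requires=frozenset({"T", "P", "constants"}),
        ),
        ModelDefinition(
            "chrastil",
            ("kappa", "E0", "E1"),
            bounds=((1.0, 20.0), (-200.0, 100.0), (-20000.0, 0.0)),
            predict=predict_chrastil,
            requires=frozenset({"T", "rho1"}),
        ),
        ModelDefinition(
            "r_chrastil",
            ("kappa_p", "F0", "F1"),
            bounds=((1.0, 20.0), (-300.0, 100.0), (-20000.0, 0.0)),
            predict=predict_r_chrastil,
            requires=frozenset({"T", "rho1", "constants"}),
        ),
        ModelDefinition(
            "bartle",
            ("G0", "G1", "G2"),
            bounds=((-100.0, 100.0), (-30000.0, 0.0), (-1.0, 1.0)),
            predict=predict_bartle,
            requires=frozenset({"T", "P", "rho1", "constants"}),
        ),
        ModelDefinition(
            "mt",
            ("H0", "H1", "H2"),
            bounds=((-50000.0, 50000.0), (-100.0, 100.0), (-200.0, 200.0)),
            predict=predict_mt,
            requires=frozenset({"T", "P", "rho1"}),
        ),
        ModelDefinition(
            "new_model_textual",
            ("dCp", "a11", "a22"),
            bounds=((-1.0e6, 1.0e6), (0.0, 1.0e9), (0.0, 1.0e9)),
            predict=predict_new_model_textual,
            requires=frozenset({"T", "rho1", "constants"}),
            log_sample=(False, True, True),
        ),
    ]
}

#: the eight correlations of the study, in presentation order
STUDY_MODELS = (
    "new_model",
    "alwi_garlapati",
    "sodeifian",
    "reddy_garlapati",
    "chrastil",
    "r_chrastil",
    "bartle",
    "mt",
)


def get_model(model_id: str) -> ModelDefinition:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model '{model_id}'; known: {sorted(MODELS)}"
        ) from None
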