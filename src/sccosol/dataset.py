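"""Solubility data handling: records, the packaged isothermal dataset, CSV I/O,
and the sampling-loop arithmetic that converts assayed concentrations to
equilibrium mole fractions.

The packaged dataset (``builtin:table2``) holds 24 equilibrium solubility
measurements of pantoprazole sodium sesquihydrate in supercritical CO2 on a
4 temperature x 6 pressure grid (308-338 K, 12-27 MPa), with the CO2 density
at each state point taken from standard reference tables.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SolubilityRecord",
    "SolubilityDataset",
    "SubstanceConstants",
    "ValidationError",
    "load_dataset",
    "write_csv",
    "load_constants",
    "mole_fraction_from_sampling",
    "solubility_gL",
    "BUILTIN_TABLE2",
    "CSV_HEADER",
]

BUILTIN_TABLE2 = "builtin:table2"

CSV_HEADER = [
    "temperature_K",
    "pressure_MPa",
    "density_kg_m3",
    "mole_fraction",
    "solubility_g_L",
    "std_dev",
    "expanded_U",
]

GAS_CONSTANT = 8.314  # J/(mol K)


class ValidationError(ValueError):
    """A dataset row or constant violates a physical invariant."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium measurement: (T, P, CO2 density, solute mole fraction).

    Units are fixed package-wide: temperature in K, pressure in MPa, density
    in kg/m3, mole fraction dimensionless. Unit conversions happen only inside
    individual correlation models, at their own convention boundary.
    """

    temperature: float
    pressure: float
    co2_density: float
    mole_fraction: float
    solubility_gL: float | None = None
    std_dev_y2: float | None = None
    expanded_uncertainty_y2: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise ValidationError(f"pressure must be > 0 MPa, got {self.pressure}")
        if not self.co2_density > 0:
            raise ValidationError(f"co2_density must be > 0 kg/m3, got {self.co2_density}")
        if not 0.0 < self.mole_fraction < 1.0:
            raise ValidationError(
                f"mole_fraction must lie in (0, 1), got {self.mole_fraction}"
            )
        if self.solubility_gL is not None and not self.solubility_gL > 0:
            raise ValidationError(f"solubility_gL must be > 0, got {self.solubility_gL}")


@dataclass(frozen=True)
class SolubilityDataset:
    """An ordered collection of solubility records, sorted by (T, P)."""

    records: tuple[SolubilityRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.records, key=lambda r: (r.temperature, r.pressure))
        )
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    @property
    def temperatures(self) -> tuple[float, ...]:
        """Distinct temperatures, ascending."""
        return tuple(sorted({r.temperature for r in self.records}))

    def isotherm(self, temperature: float) -> "SolubilityDataset":
        recs = tuple(r for r in self.records if r.temperature == temperature)
        if not recs:
            raise KeyError(f"no records at T = {temperature} K")
        return SolubilityDataset(recs, label=f"{self.label}@{temperature:g}K")

    def isotherms(self) -> dict[float, "SolubilityDataset"]:
        return {t: self.isotherm(t) for t in self.temperatures}

    def arrays(self):
        """(T, P, rho1, y2) as parallel numpy arrays."""
        import numpy as np

        T = np.array([r.temperature for r in self.records])
        P = np.array([r.pressure for r in self.records])
        rho = np.array([r.co2_density for r in self.records])
        y = np.array([r.mole_fraction for r in self.records])
        return T, P, rho, y


@dataclass(frozen=True)
class SubstanceConstants:
    """Physical constants of the solute and the supercritical solvent.

    Defaults describe pantoprazole sodium sesquihydrate (molar mass
    432.44 g/mol, melting point 412 K, crystal molar volume
    2.8202e-4 m3/mol) in CO2 (standard critical constants). The Bartle
    reference state (0.1 MPa, 700 kg/m3) and the reformulated-Chrastil
    standard-state fugacity (0.1 MPa) follow each model's original
    convention; fitted-model quality is invariant to these choices.
    """

    solute_molar_mass: float = 432.44       # g/mol
    solute_melting_temperature: float = 412.0  # K
    solute_molar_volume: float = 2.8202e-4  # m3/mol
    solvent_molar_mass: float = 44.01       # g/mol
    solvent_Tc: float = 304.13              # K
    solvent_Pc: float = 7.377               # MPa
    solvent_rhoc: float = 467.6             # kg/m3
    gas_constant: float = GAS_CONSTANT      # J/(mol K)
    bartle_Pref: float = 0.1                # MPa
    bartle_rhoref: float = 700.0            # kg/m3
    rchrastil_f0: float = 0.1               # MPa, standard-state fugacity

    def __post_init__(self) -> None:
        for name in (
            "solute_molar_mass",
            "solute_melting_temperature",
            "solute_molar_volume",
            "solvent_molar_mass",
            "solvent_Tc",
            "solvent_Pc",
            "solvent_rhoc",
            "gas_constant",
            "bartle_Pref",
            "bartle_rhoref",
            "rchrastil_f0",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


def load_constants(path: str | Path | None = None, **overrides) -> SubstanceConstants:
    """Build SubstanceConstants from an optional YAML file plus keyword overrides.

    The YAML file maps field names to numbers; unknown keys are rejected.
    """
    values: dict = {}
    if path is not None:
        import yaml

        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"constants file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(SubstanceConstants.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown constant name(s): {sorted(unknown)}")
    return SubstanceConstants(**values)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_row(row: dict[str, str], line_no: int) -> SolubilityRecord:
    def num(col: str, required: bool = True) -> float | None:
        raw = (row.get(col) or "").strip()
        if raw == "":
            if required:
                raise ValidationError(f"row {line_no}: missing value in column '{col}'")
            return None
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"row {line_no}: non-numeric value '{raw}' in column '{col}'"
            ) from None

    try:
        return SolubilityRecord(
            temperature=num("temperature_K"),
            pressure=num("pressure_MPa"),
            co2_density=num("density_kg_m3"),
            mole_fraction=num("mole_fraction"),
            solubility_gL=num("solubility_g_L", required=False),
            std_dev_y2=num("std_dev", required=False),
            expanded_uncertainty_y2=num("expanded_U", required=False),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {line_no}: {exc}") from None


def _read_csv(fh: Iterable[str], label: str) -> SolubilityDataset:
    reader = csv.DictReader(fh)
    missing = set(CSV_HEADER[:4]) - set(reader.fieldnames or ())
    if missing:
        raise ValidationError(f"missing required column(s): {sorted(missing)}")
    records = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    if not records:
        raise ValidationError("dataset contains no records")
    return SolubilityDataset(tuple(records), label=label)


def load_dataset(path: str | Path) -> SolubilityDataset:
    """Read a solubility dataset from CSV, or the packaged 24-point dataset
    via the key ``builtin:table2``. Records are validated and sorted by (T, P).
    """
    if str(path) == BUILTIN_TABLE2:
        ref = importlib.resources.files("sccosol").joinpath("data/table2.csv")
        with ref.open("r") as fh:
            ds = _read_csv(fh, label="table2")
        _check_builtin(ds)
        return ds
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such dataset file: {p}")
    with open(p, newline="") as fh:
        return _read_csv(fh, label=p.stem)


def _check_builtin(ds: SolubilityDataset) -> None:
    """Structural sanity checks on the packaged dataset."""
    assert len(ds) == 24, "builtin dataset must hold 24 records"
    for t, iso in ds.isotherms().items():
        dens = [r.co2_density for r in iso.records]
        if not all(a < b for a, b in zip(dens, dens[1:])):
            raise ValidationError(f"density not increasing with pressure at {t} K")
    for p in sorted({r.pressure for r in ds.records}):
        col = sorted(
            (r for r in ds.records if r.pressure == p), key=lambda r: r.temperature
        )
        dens = [r.co2_density for r in col]
        if not all(a > b for a, b in zip(dens, dens[1:])):
            raise ValidationError(f"density not decreasing with temperature at {p} MPa")


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(x)


def write_csv(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset using the package CSV dialect (full float precision,
    so a write/load round trip reproduces record values exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in dataset.records:
            writer.writerow(
                [
                    _fmt(r.temperature),
                    _fmt(r.pressure),
                    _fmt(r.co2_density),
                    _fmt(r.mole_fraction),
                    _fmt(r.solubility_gL),
                    _fmt(r.std_dev_y2),
                    _fmt(r.expanded_uncertainty_y2),
                ]
            )


# ---------------------------------------------------------------------------
# Sampling-loop arithmetic


def mole_fraction_from_sampling(
    Cs: float, Vs: float, Vl: float, rho: float, Ms: float, Mco2: float
) -> float:
    """Equilibrium mole fraction from the sampling-loop mass balance.

    The saturated fluid in a loop of volume ``Vl`` (L) holds
    ``n_CO2 = Vl * rho / Mco2`` moles of solvent (``rho`` in g/L); the
    collected sample of volume ``Vs`` (L) assayed at concentration ``Cs``
    (g/L) holds ``n_solute = Cs * Vs / Ms`` moles of solute. Returns
    ``y2 = n_solute / (n_solute + n_CO2)``.
    """
    if Cs < 0:
        raise ValueError(f"Cs must be >= 0, got {Cs}")
    for name, val in (("Vs", Vs), ("Vl", Vl), ("rho", rho), ("Ms", Ms), ("Mco2", Mco2)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    n_solute = Cs * Vs / Ms
    n_co2 = Vl * rho / Mco2
    return n_solute / (n_solute + n_co2)


def solubility_gL(Cs: float, Vs: float, Vl: float) -> float:
    """Equilibrium solubility in g per litre of loop volume: ``Cs * Vs / Vl``."""
    if Cs < 0:
        raise ValueError(f"Cs must be >= 0, got {Cs}")
    if not Vs > 0 or not Vl > 0:
        raise ValueError("Vs and Vl must be > 0")
    return Cs * Vs / Vl
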