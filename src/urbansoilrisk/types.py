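"""Core domain types for point-sampled topsoil geochemistry surveys.

A survey is a table of samples: an id, projected planar coordinates in
metres, strictly positive element concentrations (harmonized to mg/kg),
and a unitless pH. Everything downstream (baselines, contamination
indices, log-ratio analysis, risk) consumes this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 15 potentially toxic elements tracked by default.
DEFAULT_PTES = [
    "As", "Be", "Cd", "Co", "Cr", "Cu", "Hg", "Mo",
    "Ni", "Pb", "Sb", "Sn", "Tl", "V", "Zn",
]

#: Default normalizing element (low-variability lithogenic reference).
DEFAULT_NORMALIZER = "Fe"

VALID_UNITS = ("mg/kg", "ug/kg", "%")

#: Multiplicative factor taking a value in the given unit to mg/kg.
_TO_MGKG = {"mg/kg": 1.0, "ug/kg": 1e-3, "%": 1e4}


class ValidationError(ValueError):
    """A survey or configuration violates a structural invariant."""


@dataclass
class UnitSpec:
    """Declared input unit per element column.

    Elements not listed are assumed to already be in mg/kg.
    """

    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, u in self.units.items():
            if u not in VALID_UNITS:
                raise ValidationError(f"unknown unit {u!r} for element {el!r}; "
                                      f"expected one of {VALID_UNITS}")

    def factor(self, element: str) -> float:
        return _TO_MGKG[self.units.get(element, "mg/kg")]


#: Conventional field units: Hg reported in μg/kg, Fe in weight %.
DEFAULT_UNITS = UnitSpec({"Hg": "ug/kg", "Fe": "%"})


@dataclass
class SampleTable:
    """A harmonized point survey.

    Parameters
    ----------
    data:
        One row per sample with columns ``sample_id``, ``x``, ``y``,
        ``ph`` (optional), optional ``land_use``, plus one column per
        element. Concentrations are in mg/kg after harmonization.
    elements:
        Ordered element column names present in ``data``.
    """

    data: pd.DataFrame
    elements: list[str]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in ("sample_id", "x", "y"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        missing = [e for e in self.elements if e not in df.columns]
        if missing:
            raise ValidationError(f"element columns absent from table: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicated sample_id {dup!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite coordinates")
        for el in self.elements:
            vals = df[el].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"non-finite concentration in element {el!r}")
            if (vals <= 0).any():
                bad = df.loc[vals <= 0, "sample_id"].iloc[0]
                raise ValidationError(
                    f"non-positive concentration: sample {bad!r}, element {el!r} "
                    "(compositional data must be strictly positive)")

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected x/y in metres."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def conc(self, element: str) -> np.ndarray:
        if element not in self.data.columns:
            raise KeyError(f"element {element!r} not in survey")
        return self.data[element].to_numpy(dtype=float)

    def composition(self, parts: list[str]) -> np.ndarray:
        """(n, D) strictly positive matrix over the requested parts."""
        return self.data[list(parts)].to_numpy(dtype=float)

    @property
    def ph(self) -> np.ndarray:
        if "ph" not in self.data.columns:
            raise KeyError("survey has no ph column")
        return self.data["ph"].to_numpy(dtype=float)


def harmonize(df: pd.DataFrame, elements: list[str], units: UnitSpec,
              detection_limits: dict[str, float] | None = None) -> pd.DataFrame:
    """Convert element columns to mg/kg and impute sub-DL values as DL/2.

    Idempotent only when applied with the declared units once; callers
    should harmonize exactly at ingest. Detection limits are given in
    the *input* unit of each element.
    """
    out = df.copy()
    for el in elements:
        if el not in out.columns:
            continue
        vals = out[el].to_numpy(dtype=float)
        if detection_limits and el in detection_limits:
            dl = float(detection_limits[el])
            vals = np.where(vals < dl, dl / 2.0, vals)
        out[el] = vals * units.factor(el)
    return out


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the survey-analysis defaults."""

    elements: list[str] = field(default_factory=lambda: list(DEFAULT_PTES))
    normalizer: str = DEFAULT_NORMALIZER
    cell_size: float = 50.0            # m
    idw_power: float = 2.0
    n_neighbors: int = 12
    ca_segments: int = 4
    mc_iterations: int = 50_000
    seed: int = 0
    scenario_path: str | None = None
    toxicity_path: str | None = None

    def __post_init__(self) -> None:
        if self.mc_iterations < 1:
            raise ValidationError("mc_iterations must be >= 1")
        if self.ca_segments < 2:
            raise ValidationError("ca_segments must be >= 2")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
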