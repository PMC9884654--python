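"""Normalizer-based contamination indices for topsoil surveys.

For each sample and potentially toxic element i, with Fe (or another
low-variability lithogenic element) as normalizer N:

    ICI_i = (C_i / N_i) / (C-UBL_i / N-UBL_i)

i.e. the element/normalizer ratio relative to the same ratio at the
upper baseline limits. Per sample these aggregate into

    CCI = Σ_i ICI_i                (severity)
    CCS = #{i : ICI_i ≥ 1}         (complexity: count above baseline)
    CCD = CCI · CCS                (cumulative contamination degree)

so a sample exceeding no baseline has CCD = 0 regardless of CCI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spatial, univariate
from .types import SampleTable, ValidationError

__all__ = [
    "ContaminationRecord", "individual_contamination_index",
    "cumulative_contamination_index", "cumulative_contamination_score",
    "cumulative_contamination_degree", "contamination_records",
    "contamination_pipeline",
]


@dataclass
class ContaminationRecord:
    sample_id: str
    ici: dict[str, float]
    cci: float
    ccs: int
    ccd: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ici.values()):
            raise ValidationError("ICI values must be positive")
        if not np.isclose(self.cci, sum(self.ici.values())):
            raise ValidationError("CCI must equal the sum of ICIs")
        if self.ccd != self.cci * self.ccs:
            raise ValidationError("CCD must equal CCI·CCS")


def individual_contamination_index(c_i: float, n_i: float,
                                   c_ubl: float, n_ubl: float) -> float:
    """ICI of one element in one sample (all arguments > 0)."""
    for name, v in (("concentration", c_i), ("normalizer", n_i),
                    ("element UBL", c_ubl), ("normalizer UBL", n_ubl)):
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    return (c_i / n_i) / (c_ubl / n_ubl)


def cumulative_contamination_index(ici: dict[str, float],
                                   elements: list[str] | None = None) -> float:
    """Sum of the per-element ICIs."""
    if not ici:
        raise ValidationError("empty ICI vector")
    if elements is not None:
        missing = [e for e in elements if e not in ici]
        if missing:
            raise ValidationError(f"ICI missing for elements: {missing}")
        return float(sum(ici[e] for e in elements))
    return float(sum(ici.values()))


def cumulative_contamination_score(ici: dict[str, float],
                                   elements: list[str] | None = None) -> int:
    """Count of elements at or above baseline (ICI ≥ 1, boundary in)."""
    if not ici:
        raise ValidationError("empty ICI vector")
    keys = elements if elements is not None else list(ici)
    missing = [e for e in keys if e not in ici]
    if missing:
        raise ValidationError(f"ICI missing for elements: {missing}")
    return int(sum(1 for e in keys if ici[e] >= 1.0))


def cumulative_contamination_degree(cci: float, ccs: int) -> float:
    """CCD = CCI · CCS."""
    if cci <= 0:
        raise ValidationError("CCI must be positive")
    if ccs < 0 or int(ccs) != ccs:
        raise ValidationError("CCS must be a non-negative integer")
    return cci * ccs


def contamination_records(samples: SampleTable,
                          elements: list[str] | None = None,
                          normalizer: str = "Fe",
                          ubls: dict[str, float] | None = None,
                          ) -> list[ContaminationRecord]:
    """Per-sample ICI/CCI/CCS/CCD.

    UBLs default to local baselines computed from the survey itself;
    pass ``ubls`` (element → UBL, must include the normalizer) to use
    external baselines. The normalizer is excluded from the indexed
    element set.
    """
    elements = [e for e in (elements or samples.elements) if e != normalizer]
    if normalizer not in samples.data.columns:
        raise ValidationError(f"normalizer {normalizer!r} absent from survey")
    if ubls is None:
        ubls = {el: univariate.summarize_element(samples.conc(el), el).ubl
                for el in [*elements, normalizer]}
    missing = [e for e in [*elements, normalizer] if e not in ubls]
    if missing:
        raise ValidationError(f"UBL missing for: {missing}")

    n_vec = samples.conc(normalizer)
    n_ubl = ubls[normalizer]
    recs = []
    for i, sid in enumerate(samples.sample_ids):
        ici = {el: individual_contamination_index(
                   samples.conc(el)[i], n_vec[i], ubls[el], n_ubl)
               for el in elements}
        cci = cumulative_contamination_index(ici, elements)
        ccs = cumulative_contamination_score(ici, elements)
        recs.append(ContaminationRecord(str(sid), ici, cci, ccs,
                                        cumulative_contamination_degree(cci, ccs)
                                        if ccs > 0 else 0.0))
    return recs


@dataclass
class ContaminationResult:
    records: list[ContaminationRecord]
    table: pd.DataFrame
    cci_breaks: spatial.ClassBreaks | None
    ccs_breaks: spatial.ClassBreaks | None
    ccd_grid: spatial.Grid | None
    ccd_breaks: spatial.ClassBreaks | None = field(default=None)


def contamination_pipeline(samples: SampleTable,
                           elements: list[str] | None = None,
                           normalizer: str = "Fe",
                           ubls: dict[str, float] | None = None,
                           cell_size: float = 50.0,
                           idw_power: float = 2.0,
                           n_neighbors: int = 12,
                           n_jenks_classes: int = 5,
                           n_ca_classes: int = 4,
                           make_grid: bool = True) -> ContaminationResult:
    """Records for every sample, Jenks classes for the CCI/CCS dot maps,
    and a MIDW-interpolated CCD surface classed by the C–A method."""
    recs = contamination_records(samples, elements, normalizer, ubls)
    table = pd.DataFrame(
        {"sample_id": [r.sample_id for r in recs],
         "cci": [r.cci for r in recs],
         "ccs": [r.ccs for r in recs],
         "ccd": [r.ccd for r in recs]})

    def _jenks_or_none(vals, k):
        try:
            return spatial.jenks_breaks(np.asarray(vals, float), k)
        except ValidationError:
            return None

    cci_breaks = _jenks_or_none(table["cci"], n_jenks_classes)
    ccs_breaks = _jenks_or_none(table["ccs"], min(n_jenks_classes,
                                                  table["ccs"].nunique()))
    ccd_grid = ccd_breaks = None
    if make_grid:
        spec = spatial.GridSpec.from_samples(samples, cell_size)
        k = min(n_neighbors, len(samples.data))
        ccd_grid = spatial.midw_interpolate(
            samples, "", spec, power=idw_power, k=k,
            values=table["ccd"].to_numpy())
        try:
            ccd_breaks = spatial.ca_breaks(ccd_grid, n_ca_classes)
        except ValidationError:
            ccd_breaks = None  # flat or degenerate surface
    return ContaminationResult(recs, table, cci_breaks, ccs_breaks,
                               ccd_grid, ccd_breaks)
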