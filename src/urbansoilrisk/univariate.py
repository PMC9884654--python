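"""Per-element summary statistics, geochemical baselines, and QC metrics.

The upper baseline limit (UBL) of an element is the outlier-resistant
upper edge of its local background distribution:

    UBL = median + 2 · MAD

where MAD is the *raw* median absolute deviation — no 1.4826 normal
consistency factor is applied. Kurtosis follows the Pearson convention
(a normal distribution scores 3).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleTable, ValidationError

__all__ = ["ElementSummary", "summarize_element", "summarize_table",
           "upper_baseline", "coefficient_of_variation", "mad", "qc_metrics"]


@dataclass
class ElementSummary:
    element: str
    n: int
    min: float
    max: float
    mean: float
    median: float
    mad: float
    sd: float
    variance: float
    kurtosis: float     # Pearson: normal = 3
    skewness: float
    cv_percent: float
    ubl: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mad(values: np.ndarray) -> float:
    """Raw median absolute deviation, median(|x − median(x)|)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def upper_baseline(median: float, mad_value: float) -> float:
    """UBL = median + 2·MAD."""
    if mad_value < 0:
        raise ValidationError("MAD cannot be negative")
    return median + 2.0 * mad_value


def coefficient_of_variation(sd: float, mean: float) -> float:
    """CV in percent, 100·sd/mean."""
    if mean <= 0:
        raise ValidationError("CV requires a positive mean")
    return 100.0 * sd / mean


def summarize_element(values: np.ndarray, element: str = "") -> ElementSummary:
    """Full univariate summary of one element's concentration vector."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValidationError("need at least 2 finite values to summarize")
    if (v <= 0).any():
        raise ValidationError(f"non-positive concentrations in {element!r}")
    med = float(np.median(v))
    m = mad(v)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return ElementSummary(
        element=element,
        n=len(v),
        min=float(v.min()),
        max=float(v.max()),
        mean=mean,
        median=med,
        mad=m,
        sd=sd,
        variance=sd ** 2,
        kurtosis=float(stats.kurtosis(v, fisher=False, bias=False)),
        skewness=float(stats.skew(v, bias=False)),
        cv_percent=coefficient_of_variation(sd, mean),
        ubl=upper_baseline(med, m),
    )


def summarize_table(samples: SampleTable,
                    elements: list[str] | None = None) -> pd.DataFrame:
    """One summary row per element (and pH when present), indexed by
    element name — the survey's baseline table."""
    elements = list(elements) if elements is not None else list(samples.elements)
    rows = [summarize_element(samples.conc(el), el).as_dict() for el in elements]
    df = pd.DataFrame(rows).set_index("element")
    return df


def qc_metrics(duplicate_pairs: list[tuple[float, float]] | None = None,
               certified: dict[str, tuple[float, float]] | None = None) -> dict:
    """Analytical QA/QC.

    ``duplicate_pairs`` are (a, b) replicate measurements; precision is
    the relative percent difference RPD = 100·|a−b| / ((a+b)/2).
    ``certified`` maps element → (measured, reference); accuracy error
    is 100·|measured − certified| / certified.
    """
    out: dict = {}
    if duplicate_pairs is not None:
        rpds = []
        for a, b in duplicate_pairs:
            if a + b == 0:
                raise ValidationError("duplicate pair sums to zero")
            rpds.append(100.0 * abs(a - b) / ((a + b) / 2.0))
        out["rpd_percent"] = rpds
    if certified is not None:
        acc = {}
        for el, (meas, ref) in certified.items():
            if ref <= 0:
                raise ValidationError(f"certified value for {el!r} must be positive")
            acc[el] = 100.0 * abs(meas - ref) / ref
        out["accuracy_error_percent"] = acc
    return out
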