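"""Deterministic and Monte Carlo human-health risk assessment for soil
ingestion and dust inhalation.

Non-carcinogenic: dose D = C·IR·AF·EF/BW (mg/kg/day) for ingestion;
for inhalation the exposure concentration C/PEF·EF (mg/m³) is compared
to the reference concentration instead, so body weight cancels. The
hazard quotient is HQ = D/RfD; HQs below 0.2 are screened out, the ones
at or above 0.2 that share a target organ sum to the hazard index HI,
and HI ≥ 1 is unacceptable.

Carcinogenic: ILCR = D·SF (ingestion, with lifetime averaging time) or
air concentration in μg/m³ × IUR (inhalation). ILCR below 1e−6 is no
risk, between 1e−6 and 1e−4 tolerable, above 1e−4 unacceptable.

The stochastic path fits a parametric distribution to each element's
observed concentrations, then propagates Monte Carlo draws through the
same equations; results are "certainties", the percent of iterations
meeting or exceeding the regulatory threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleTable, ValidationError

__all__ = [
    "ExposureScenario", "ToxRecord", "RiskResult",
    "exposure_factor", "dose", "hazard_quotient", "hazard_index", "ilcr",
    "fit_concentration_distribution", "monte_carlo_risk",
    "deterministic_risk", "HQ_THRESHOLD", "HI_THRESHOLD", "ILCR_THRESHOLD",
]

HQ_THRESHOLD = 0.2
HI_THRESHOLD = 1.0
ILCR_THRESHOLD = 1e-6
ILCR_UNACCEPTABLE = 1e-4
DEFAULT_LIFETIME_YEARS = 70.0


# ---------------------------------------------------------------------------
# Scenario and toxicity records
# ---------------------------------------------------------------------------

@dataclass
class ExposureScenario:
    """One receptor/pathway combination.

    ``intake_rate`` is kg soil/day for ingestion and m³ air/day for
    inhalation; ``pef`` (m³/kg) converts soil to airborne-dust
    concentration and is required for inhalation only.
    """

    receptor: str                     # "child" | "adult"
    pathway: str                      # "ingestion" | "inhalation"
    intake_rate: float
    bioavailability: float = 1.0      # AF; 1 = worst-case screening
    frequency_days: float = 350.0     # F, days/year
    duration_years: float = 6.0       # ED
    body_weight: float = 15.0         # BW, kg
    pef: float | None = None          # m³/kg, inhalation only
    lifetime_years: float = DEFAULT_LIFETIME_YEARS

    def __post_init__(self) -> None:
        # YAML 1.1 parses exponents like 1.36e9 as strings; coerce
        for name in ("intake_rate", "bioavailability", "frequency_days",
                     "duration_years", "body_weight", "lifetime_years"):
            setattr(self, name, float(getattr(self, name)))
        if self.pef is not None:
            self.pef = float(self.pef)
        if not 0 < self.bioavailability <= 1:
            raise ValidationError("AF must be in (0, 1]")
        if not 0 < self.frequency_days <= 365:
            raise ValidationError("exposure frequency must be in (0, 365]")
        for name in ("intake_rate", "duration_years", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.pathway not in ("ingestion", "inhalation"):
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if self.pathway == "inhalation" and not self.pef:
            raise ValidationError("inhalation scenario requires a PEF")


@dataclass
class ToxRecord:
    """Toxicological reference values for one element; any subset may be
    present (absent routes are skipped in the assessment)."""

    element: str
    rfd: float | None = None          # oral reference dose, mg/kg/day
    rfc: float | None = None          # inhalation ref. concentration, mg/m³
    sf: float | None = None           # oral slope factor, (mg/kg/day)⁻¹
    iur: float | None = None          # inhalation unit risk, (μg/m³)⁻¹
    target_organs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if all(v is None for v in (self.rfd, self.rfc, self.sf, self.iur)):
            raise ValidationError(
                f"{self.element}: at least one toxicity value required")


# ---------------------------------------------------------------------------
# Core equations
# ---------------------------------------------------------------------------

def exposure_factor(frequency_days: float, duration_years: float,
                    carcinogenic: bool = False,
                    lifetime_years: float = DEFAULT_LIFETIME_YEARS) -> float:
    """EF = F·ED/AT. For non-carcinogens AT = ED·365 so EF = F/365; for
    carcinogens AT is the lifetime, AT = LT·365."""
    if not 0 < frequency_days <= 365:
        raise ValidationError("frequency must be in (0, 365] days/year")
    if duration_years <= 0:
        raise ValidationError("duration must be positive")
    at_years = lifetime_years if carcinogenic else duration_years
    return frequency_days * duration_years / (at_years * 365.0)


def dose(conc_mgkg, scenario: ExposureScenario,
         carcinogenic: bool = False):
    """Daily dose (ingestion, mg/kg/day) or exposure concentration
    (inhalation, mg/m³) for soil concentration(s) in mg/kg."""
    c = np.asarray(conc_mgkg, dtype=float)
    if (c <= 0).any():
        raise ValidationError("concentration must be positive")
    ef = exposure_factor(scenario.frequency_days, scenario.duration_years,
                         carcinogenic, scenario.lifetime_years)
    if scenario.pathway == "ingestion":
        out = (c * scenario.intake_rate * scenario.bioavailability * ef
               / scenario.body_weight)
    else:
        # soil → dust air concentration; paired with RfC/IUR, so BW-free
        out = c / scenario.pef * scenario.bioavailability * ef
    return out if out.ndim else float(out)


def hazard_quotient(d, reference: float):
    """HQ = D/RfD (or exposure concentration / RfC)."""
    if reference is None or reference <= 0:
        raise ValidationError("reference value must be positive")
    out = np.asarray(d, dtype=float) / reference
    return out if out.ndim else float(out)


def hazard_index(hqs: dict[str, float | np.ndarray],
                 organ_map: dict[str, list[str]],
                 threshold: float = HQ_THRESHOLD) -> dict[str, np.ndarray]:
    """Per-organ HI: the sum of HQs ≥ ``threshold`` over the elements
    mapped to that organ. Screened-out HQs contribute 0; an organ whose
    every element screens out gets HI = 0."""
    out: dict[str, np.ndarray] = {}
    for organ, els in organ_map.items():
        total = None
        for el in els:
            if el not in hqs:
                continue
            hq = np.asarray(hqs[el], dtype=float)
            contrib = np.where(hq >= threshold, hq, 0.0)
            total = contrib if total is None else total + contrib
        if total is None:
            total = np.asarray(0.0)
        out[organ] = total
    return out


def ilcr(d, slope: float):
    """ILCR = D·SF (or μg/m³ air concentration × IUR)."""
    if slope is None or slope <= 0:
        raise ValidationError("slope factor must be positive")
    out = np.asarray(d, dtype=float) * slope
    return out if out.ndim else float(out)


def ilcr_class(value: float) -> str:
    if value < ILCR_THRESHOLD:
        return "no risk"
    if value <= ILCR_UNACCEPTABLE:
        return "tolerable"
    return "unacceptable"


# ---------------------------------------------------------------------------
# Concentration distributions
# ---------------------------------------------------------------------------

_FAMILIES = {
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
    "normal": stats.norm,
}


def _anderson_darling(values: np.ndarray, dist, params) -> float:
    """A² statistic of the fitted distribution against the sample."""
    x = np.sort(values)
    n = len(x)
    cdf = np.clip(dist.cdf(x, *params), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(cdf)
                                             + np.log1p(-cdf[::-1]))))


@dataclass
class FittedDistribution:
    family: str
    params: tuple
    statistic: float

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.params[0])
        if self.family == "empirical":
            return rng.choice(np.asarray(self.params[0]), size=size)
        d = _FAMILIES[self.family]
        return d.rvs(*self.params, size=size, random_state=rng)

    def median(self) -> float:
        if self.family == "point":
            return float(self.params[0])
        if self.family == "empirical":
            return float(np.median(self.params[0]))
        return float(_FAMILIES[self.family].median(*self.params))


def fit_concentration_distribution(values,
                                   families: tuple[str, ...] = (
                                       "lognormal", "gamma",
                                       "weibull", "normal"),
                                   ) -> FittedDistribution:
    """Best-fitting family by the Anderson–Darling statistic.

    Positive-support families are fitted with the location pinned at 0.
    A constant vector yields a point mass; if every fit fails, the
    empirical distribution is resampled instead.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 8:
        raise ValidationError("need at least 8 values to fit a distribution")
    if np.ptp(v) == 0:
        return FittedDistribution("point", (float(v[0]),), 0.0)

    best: FittedDistribution | None = None
    for name in families:
        d = _FAMILIES[name]
        try:
            params = (d.fit(v) if name == "normal"
                      else d.fit(v, floc=0.0))
            a2 = _anderson_darling(v, d, params)
        except Exception:
            continue
        if np.isfinite(a2) and (best is None or a2 < best.statistic):
            best = FittedDistribution(name, tuple(params), a2)
    if best is None:
        return FittedDistribution("empirical", (v.copy(),), float("inf"))
    return best


# ---------------------------------------------------------------------------
# Monte Carlo assessment
# ---------------------------------------------------------------------------

@dataclass
class RiskResult:
    """Monte Carlo risk distributions and exceedance certainties.

    ``hq``/``hi``/``ilcr`` tables carry one row per (receptor, pathway,
    element-or-organ) with summary statistics, the certainty in percent
    and its binomial 95% half-width.
    """

    hq: pd.DataFrame
    hi: pd.DataFrame
    ilcr: pd.DataFrame
    n_iterations: int
    seed: int
    distributions: dict[str, FittedDistribution] = field(default_factory=dict)


def _certainty(values: np.ndarray, threshold: float,
               n_iter: int) -> tuple[float, float]:
    p = float(np.mean(values >= threshold))
    half = 1.96 * 100.0 * np.sqrt(max(p * (1 - p), 0.0) / n_iter)
    return 100.0 * p, half


def monte_carlo_risk(samples: SampleTable,
                     scenarios: list[ExposureScenario],
                     tox_table: dict[str, ToxRecord],
                     organ_map: dict[str, list[str]] | None = None,
                     n_iter: int = 50_000,
                     seed: int = 0) -> RiskResult:
    """Propagate fitted concentration distributions through the risk
    equations for every scenario; elements are drawn independently.

    Certainty is 100 × (iterations meeting or exceeding the threshold) /
    n_iter, reported with its 95% binomial half-width.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if not tox_table:
        raise ValidationError("empty toxicity table")
    organ_map = organ_map or {}
    rng = np.random.default_rng(seed)

    elements = [el for el in samples.elements if el in tox_table]
    fits = {el: fit_concentration_distribution(samples.conc(el))
            for el in elements}
    draws = {el: np.clip(fits[el].rvs(n_iter, rng), 1e-12, None)
             for el in elements}

    hq_rows, hi_rows, ilcr_rows = [], [], []
    for sc in scenarios:
        key = dict(receptor=sc.receptor, pathway=sc.pathway)
        hqs: dict[str, np.ndarray] = {}
        for el in elements:
            tox = tox_table[el]
            ref = tox.rfd if sc.pathway == "ingestion" else tox.rfc
            if ref is not None and ref > 0:
                d = dose(draws[el], sc, carcinogenic=False)
                hq = hazard_quotient(d, ref)
                hqs[el] = hq
                cert, half = _certainty(hq, HQ_THRESHOLD, n_iter)
                hq_rows.append({**key, "element": el,
                                "median": float(np.median(hq)),
                                "max": float(hq.max()),
                                "skewness": float(stats.skew(hq)),
                                "certainty_percent": cert,
                                "certainty_ci95_halfwidth": half})
            slope = tox.sf if sc.pathway == "ingestion" else tox.iur
            if slope is not None and slope > 0:
                d = dose(draws[el], sc, carcinogenic=True)
                if sc.pathway == "inhalation":
                    d = d * 1e3                  # mg/m³ → μg/m³ for IUR
                il = ilcr(d, slope)
                cert, half = _certainty(il, ILCR_THRESHOLD, n_iter)
                ilcr_rows.append({**key, "element": el,
                                  "median": float(np.median(il)),
                                  "max": float(il.max()),
                                  "certainty_percent": cert,
                                  "certainty_ci95_halfwidth": half})
        for organ, hi_vals in hazard_index(hqs, organ_map).items():
            hi_vals = np.broadcast_to(np.asarray(hi_vals, float), (n_iter,))
            cert, half = _certainty(hi_vals, HI_THRESHOLD, n_iter)
            hi_rows.append({**key, "organ": organ,
                            "median": float(np.median(hi_vals)),
                            "max": float(hi_vals.max()),
                            "certainty_percent": cert,
                            "certainty_ci95_halfwidth": half})

    return RiskResult(pd.DataFrame(hq_rows), pd.DataFrame(hi_rows),
                      pd.DataFrame(ilcr_rows), n_iter, seed, fits)


def deterministic_risk(conc: dict[str, float],
                       scenario: ExposureScenario,
                       tox_table: dict[str, ToxRecord],
                       organ_map: dict[str, list[str]] | None = None) -> dict:
    """Single-value screening at fixed concentrations (e.g. survey
    medians or maxima): HQ and ILCR per element, HI per organ."""
    hqs: dict[str, float] = {}
    ilcrs: dict[str, float] = {}
    for el, c in conc.items():
        tox = tox_table.get(el)
        if tox is None:
            continue
        ref = tox.rfd if scenario.pathway == "ingestion" else tox.rfc
        if ref is not None and ref > 0:
            hqs[el] = hazard_quotient(dose(c, scenario), ref)
        slope = tox.sf if scenario.pathway == "ingestion" else tox.iur
        if slope is not None and slope > 0:
            d = dose(c, scenario, carcinogenic=True)
            if scenario.pathway == "inhalation":
                d = d * 1e3
            ilcrs[el] = ilcr(d, slope)
    his = {organ: float(v) for organ, v
           in hazard_index(hqs, organ_map or {}).items()}
    return {"hq": hqs, "hi": his,
            "ilcr": ilcrs,
            "ilcr_class": {el: ilcr_class(v) for el, v in ilcrs.items()}}
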