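"""Compositional data analysis for geochemical surveys.

Element concentrations are parts of a whole: only relative information
is meaningful, and raw covariances carry spurious (closure) correlation.
All multivariate work here therefore happens in log-ratio coordinates:

* clr — centred log-ratio, ln(x_j / g(x)); zero-sum, D coordinates.
* ilr — isometric log-ratio, D−1 unconstrained orthonormal coordinates
  built from a contrast (basis) matrix.
* balances — the special ilr coordinates of a sequential binary
  partition (SBP). A row splitting r "+" parts from s "−" parts gives

      b = sqrt(r·s/(r+s)) · ln( g(plus parts) / g(minus parts) )

PCA is robustified with a high-breakdown covariance (MinCovDet) on the
ilr coordinates, with soil pH appended as a z-scored external
(non-compositional) variable, and results are back-transformed to clr
space where loadings are interpretable per element.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import MinCovDet

from .types import SampleTable, ValidationError

__all__ = [
    "SBPMatrix", "DEFAULT_SBP", "PCAResult", "BalanceSet",
    "clr_transform", "ilr_transform", "ilr_basis_from_sbp", "pivot_basis",
    "robust_pca_coda", "variable_contributions", "sbp_balances",
    "coda_pipeline",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def _as_matrix(comp) -> np.ndarray:
    x = np.asarray(comp, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if (x <= 0).any():
        raise ValidationError("compositions must be strictly positive")
    return x


def clr_transform(comp) -> np.ndarray:
    """Centred log-ratio: ln(x_j / g(x)) per part; rows sum to 0.

    Accepts a (D,) composition or an (n, D) matrix; returns the same
    shape.
    """
    x = _as_matrix(comp)
    lx = np.log(x)
    out = lx - lx.mean(axis=1, keepdims=True)
    return out[0] if np.asarray(comp).ndim == 1 else out


def pivot_basis(d: int) -> np.ndarray:
    """(D−1, D) orthonormal contrast matrix of the canonical pivot
    (Helmert-style) ilr basis."""
    if d < 2:
        raise ValidationError("need at least 2 parts")
    v = np.zeros((d - 1, d))
    for i in range(d - 1):
        r = d - i - 1                       # parts in the minus group
        coef = np.sqrt(r / (r + 1.0))
        v[i, i] = coef
        v[i, i + 1:] = -coef / r
    return v


def ilr_basis_from_sbp(sbp: "SBPMatrix") -> np.ndarray:
    """(D−1, D) orthonormal contrast matrix of the balance basis: row
    with r plus parts and s minus parts gets +a/r on the plus parts and
    −a/s on the minus parts, a = sqrt(r·s/(r+s))."""
    signs = sbp.signs
    d = signs.shape[1]
    v = np.zeros((d - 1, d))
    for i, row in enumerate(signs):
        r = int((row > 0).sum())
        s = int((row < 0).sum())
        a = np.sqrt(r * s / (r + s))
        v[i, row > 0] = a / r
        v[i, row < 0] = -a / s
    return v


def ilr_transform(comp, basis: np.ndarray) -> np.ndarray:
    """ilr coordinates clr(x) · basisᵀ for an orthonormal contrast
    matrix ``basis`` of shape (D−1, D)."""
    x = _as_matrix(comp)
    d = x.shape[1]
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (d - 1, d):
        raise ValidationError(f"basis must be ({d - 1}, {d}), got {basis.shape}")
    gram = basis @ basis.T
    if not np.allclose(gram, np.eye(d - 1), atol=1e-8):
        raise ValidationError("basis rows are not orthonormal")
    if not np.allclose(basis.sum(axis=1), 0.0, atol=1e-8):
        raise ValidationError("basis rows must be zero-sum (log-contrasts)")
    out = clr_transform(x) @ basis.T
    return out[0] if np.asarray(comp).ndim == 1 else out


# ---------------------------------------------------------------------------
# Sequential binary partition
# ---------------------------------------------------------------------------

@dataclass
class SBPMatrix:
    """A sequential binary partition over ``parts``: D−1 sign rows, each
    splitting one of the groups produced higher up into a +1 and a −1
    subgroup (0 = not involved)."""

    parts: list[str]
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        d = len(self.parts)
        if self.signs.shape != (d - 1, d):
            raise ValidationError(
                f"SBP must have shape ({d - 1}, {d}), got {self.signs.shape}")
        if not np.isin(self.signs, (-1, 0, 1)).all():
            raise ValidationError("SBP entries must be -1, 0 or +1")
        for i, row in enumerate(self.signs):
            if (row > 0).sum() == 0 or (row < 0).sum() == 0:
                raise ValidationError(f"SBP row {i + 1} lacks a + or − side")
        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        """Each row must split a group that appears as one block of some
        earlier row (the first row splits everything it involves)."""
        groups = [frozenset(np.flatnonzero(self.signs[0] != 0))]
        for i, row in enumerate(self.signs):
            involved = frozenset(np.flatnonzero(row != 0))
            if i > 0 and involved not in groups:
                raise ValidationError(
                    f"SBP row {i + 1} does not partition a group produced "
                    "by an earlier row")
            groups.append(frozenset(np.flatnonzero(row > 0)))
            groups.append(frozenset(np.flatnonzero(row < 0)))


#: The default 5-part partition over (Be, Tl, Hg, Pb, Sn): anthropogenic
#: (Hg, Pb, Sn) against geogenic (Be, Tl), then Hg against Pb+Sn, then
#: Pb against Sn, then Be against Tl.
DEFAULT_SBP = SBPMatrix(
    parts=["Be", "Tl", "Hg", "Pb", "Sn"],
    signs=np.array([
        [-1, -1, +1, +1, +1],
        [0, 0, +1, -1, -1],
        [0, 0, 0, +1, -1],
        [+1, -1, 0, 0, 0],
    ]),
)


@dataclass
class BalanceSet:
    """Per-sample balance coordinates plus their means/variances."""

    sbp: SBPMatrix
    coordinates: pd.DataFrame          # columns b1..b_{D-1}
    means: np.ndarray
    variances: np.ndarray


def sbp_balances(samples: SampleTable | pd.DataFrame | np.ndarray,
                 sbp: SBPMatrix = DEFAULT_SBP) -> BalanceSet:
    """Balance coordinates b_i = sqrt(r·s/(r+s))·ln(g(plus)/g(minus))
    for every sample and SBP row."""
    if isinstance(samples, SampleTable):
        x = samples.composition(sbp.parts)
    elif isinstance(samples, pd.DataFrame):
        missing = [p for p in sbp.parts if p not in samples.columns]
        if missing:
            raise ValidationError(f"parts absent from table: {missing}")
        x = samples[sbp.parts].to_numpy(dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
    x = _as_matrix(x)
    if x.shape[1] != len(sbp.parts):
        raise ValidationError("composition width does not match SBP parts")

    lx = np.log(x)
    cols = {}
    for i, row in enumerate(sbp.signs):
        r = int((row > 0).sum())
        s = int((row < 0).sum())
        coef = np.sqrt(r * s / (r + s))
        log_gp = lx[:, row > 0].mean(axis=1)
        log_gn = lx[:, row < 0].mean(axis=1)
        cols[f"b{i + 1}"] = coef * (log_gp - log_gn)
    coords = pd.DataFrame(cols)
    return BalanceSet(sbp, coords,
                      coords.mean().to_numpy(),
                      coords.var(ddof=1).to_numpy())


# ---------------------------------------------------------------------------
# Robust PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Robust compositional PCA back-transformed to clr space.

    ``loadings_clr`` rows are the compositional parts followed by any
    external variables; per component the compositional rows sum to 0.
    """

    variables: list[str]               # parts + external names
    parts: list[str]
    loadings_clr: np.ndarray           # (len(variables), n_components)
    scores: np.ndarray                 # (n_samples, n_components)
    explained_variance_percent: np.ndarray
    contributions_percent: np.ndarray  # (len(variables), n_components)
    contribution_cutoff_percent: float

    def flagged(self, component: int) -> list[str]:
        """Variables whose contribution to the component exceeds the
        cutoff."""
        c = self.contributions_percent[:, component]
        return [v for v, ci in zip(self.variables, c)
                if ci > self.contribution_cutoff_percent]

    def summary(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings_clr.shape[1])]
        df = pd.DataFrame(self.loadings_clr, index=self.variables, columns=cols)
        df.loc["explained_variance_%"] = self.explained_variance_percent
        return df


def robust_pca_coda(samples: SampleTable | pd.DataFrame,
                    elements: list[str],
                    external: list[str] | None = None,
                    cutoff_percent: float | None = None,
                    support_fraction: float = 0.75,
                    robust: bool = True,
                    random_state: int = 0) -> PCAResult:
    """PCA of the ilr-transformed composition with robust covariance.

    The composition over ``elements`` is ilr-transformed (pivot basis;
    the result is basis-independent after clr back-transform), external
    columns (e.g. pH) are z-scored and appended, a high-breakdown
    MinCovDet location/scatter is estimated, and its eigenvectors are
    mapped back to clr space for interpretation. Scores are the
    (robustly centred) data projected on the eigenvectors.
    """
    external = list(external or [])
    if isinstance(samples, SampleTable):
        df = samples.data
    else:
        df = samples
    missing = [c for c in [*elements, *external] if c not in df.columns]
    if missing:
        raise ValidationError(f"columns absent from survey: {missing}")
    x = df[list(elements)].to_numpy(dtype=float)
    n, d = x.shape
    if n <= d + 5:
        raise ValidationError(
            f"robust PCA needs n > D + 5 samples (n={n}, D={d})")
    if np.allclose(x / x[:, :1], (x / x[:, :1])[0], rtol=1e-12, atol=0):
        raise ValidationError("degenerate survey: all compositions equal "
                              "up to scale")

    basis = pivot_basis(d)
    z = ilr_transform(x, basis)                      # (n, d-1)
    ext = np.empty((n, 0))
    if external:
        e = df[external].to_numpy(dtype=float)
        sd = e.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("constant external variable")
        ext = (e - e.mean(axis=0)) / sd
    zz = np.hstack([z, ext])

    if robust:
        mcd = MinCovDet(support_fraction=support_fraction,
                        random_state=random_state).fit(zz)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center = zz.mean(axis=0)
        cov = np.cov(zz, rowvar=False)

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValidationError("rank-deficient covariance")
    explained = 100.0 * evals / evals.sum()

    scores = (zz - center) @ evecs

    # back-transform: ilr block of each eigenvector → clr loadings
    k = d - 1
    load_comp = basis.T @ evecs[:k, :]               # (d, n_comp)
    load_ext = evecs[k:, :]                          # (n_ext, n_comp)
    loadings = np.vstack([load_comp, load_ext])

    # sign convention: the largest-|loading| entry of each component is +
    for j in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0, keepdims=True)
    cutoff = (100.0 / len(elements)) if cutoff_percent is None else cutoff_percent

    return PCAResult(
        variables=[*elements, *external],
        parts=list(elements),
        loadings_clr=loadings,
        scores=scores,
        explained_variance_percent=explained,
        contributions_percent=contrib,
        contribution_cutoff_percent=float(cutoff),
    )


def variable_contributions(pca: PCAResult, component: int
                           ) -> tuple[pd.Series, list[str]]:
    """Percent contribution of each variable to the component,
    100·loading²/Σloadings², plus the above-cutoff variables."""
    if not 0 <= component < pca.loadings_clr.shape[1]:
        raise ValidationError(f"no component {component}")
    s = pd.Series(pca.contributions_percent[:, component],
                  index=pca.variables, name=f"PC{component + 1}")
    return s, pca.flagged(component)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class CodaResult:
    pca: PCAResult
    balances: BalanceSet
    score_grids: dict[str, object] = field(default_factory=dict)
    balance_grids: dict[str, object] = field(default_factory=dict)
    score_breaks: dict[str, object] = field(default_factory=dict)
    biplot_table: pd.DataFrame | None = None


def coda_pipeline(samples: SampleTable,
                  elements: list[str] | None = None,
                  external: list[str] = ("ph",),
                  sbp: SBPMatrix = DEFAULT_SBP,
                  ccd: np.ndarray | None = None,
                  cell_size: float = 50.0,
                  n_neighbors: int = 12,
                  make_grids: bool = True,
                  random_state: int = 0) -> CodaResult:
    """Robust PCA + SBP balances, with PC1/PC2 score maps (symmetric
    breaks) and MIDW maps of every balance coordinate. ``ccd`` attaches
    per-sample contamination degrees to the exported biplot table."""
    from . import spatial  # local import to keep module deps acyclic
    from .types import DEFAULT_NORMALIZER

    # the normalizer is not part of the analyzed composition
    elements = list(elements
                    or [e for e in samples.elements if e != DEFAULT_NORMALIZER])
    external = [e for e in external if e in samples.data.columns]
    pca = robust_pca_coda(samples, elements, external,
                          random_state=random_state)
    balances = sbp_balances(samples, sbp)

    biplot = pd.DataFrame({
        "sample_id": samples.sample_ids,
        "pc1": pca.scores[:, 0],
        "pc2": pca.scores[:, 1],
    })
    if ccd is not None:
        biplot["ccd"] = np.asarray(ccd, dtype=float)

    score_grids: dict[str, object] = {}
    balance_grids: dict[str, object] = {}
    score_breaks: dict[str, object] = {}
    if make_grids:
        spec = spatial.GridSpec.from_samples(samples, cell_size)
        k = min(n_neighbors, len(samples.data))
        for j, name in enumerate(("pc1", "pc2")):
            vals = pca.scores[:, j]
            score_grids[name] = spatial.idw_interpolate(
                samples, "", spec, k=k, values=vals)
            score_breaks[name] = spatial.symmetric_score_breaks(vals)
        for col in balances.coordinates.columns:
            balance_grids[col] = spatial.midw_interpolate(
                samples, "", spec, k=k,
                values=balances.coordinates[col].to_numpy())
    return CodaResult(pca, balances, score_grids, balance_grids,
                      score_breaks, biplot)
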