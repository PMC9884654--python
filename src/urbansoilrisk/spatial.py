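"""Raster machinery: IDW and multifractal IDW interpolation, the
concentration–area (C–A) fractal classification, Jenks natural breaks,
and symmetric score breaks.

Multifractal IDW (MIDW) sharpens ordinary IDW surfaces where the field
is locally singular. For each cell the mean value μ over square windows
of growing edge length L = 2r+1 cells (half-width r) is assumed to
scale as

    μ(L) = c · L^(α − 2)

in two dimensions: α is the local singularity exponent and c the
non-singular component — the scaling law extrapolated to the cell's own
scale L = 1. Fitting log μ against log L over a few window sizes yields
per-cell α and c; the MIDW estimate is c · L_min^(α−2) with L_min = 1,
i.e. c itself. On a non-singular field α = 2 and MIDW collapses to
plain IDW, which is exactly the behaviour the method is used for:
backgrounds are untouched, anomalies (α < 2) are enhanced rather than
smoothed away.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .types import SampleTable, ValidationError

__all__ = [
    "Grid", "GridSpec", "ClassBreaks",
    "idw_interpolate", "singularity_index", "midw_interpolate",
    "ca_breaks", "jenks_breaks", "symmetric_score_breaks",
]


@dataclass
class GridSpec:
    """Regular raster geometry: lower-left corner, cell size, shape."""

    xll: float
    yll: float
    cell_size: float
    ncols: int
    nrows: int

    @classmethod
    def from_samples(cls, samples: SampleTable, cell_size: float = 50.0,
                     pad_cells: int = 1) -> "GridSpec":
        xy = samples.coords
        xmin, ymin = xy.min(axis=0) - pad_cells * cell_size
        xmax, ymax = xy.max(axis=0) + pad_cells * cell_size
        ncols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
        nrows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
        return cls(float(xmin), float(ymin), float(cell_size), ncols, nrows)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (ncols,) and y (nrows,) center coordinates; y[0] is the
        northernmost row, matching the row order of :class:`Grid`."""
        x = self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size
        y = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return x, y


@dataclass
class Grid:
    """A raster of values; ``values[0, :]`` is the northernmost row.

    Masked cells (outside the study hull) are NaN and carry
    ``mask == False``.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray  # True where the cell is inside the study area

    def __post_init__(self) -> None:
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValidationError("grid values shape does not match spec")
        if self.mask.shape != self.values.shape:
            raise ValidationError("grid mask shape does not match values")
        inside = self.values[self.mask]
        if inside.size and not np.isfinite(inside).all():
            raise ValidationError("non-finite values inside the grid mask")

    @property
    def inside_values(self) -> np.ndarray:
        return self.values[self.mask]


def study_mask(spec: GridSpec, samples: SampleTable,
               buffer_cells: int = 1) -> np.ndarray:
    """Cells inside the convex hull of the samples, buffered by
    ``buffer_cells`` via proximity to any sample."""
    xs, ys = spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    xy = samples.coords
    try:
        hull = Delaunay(xy)
        inside = hull.find_simplex(pts) >= 0
    except Exception:  # degenerate (collinear) survey: proximity only
        inside = np.zeros(len(pts), dtype=bool)
    buf = buffer_cells * spec.cell_size
    d, _ = cKDTree(xy).query(pts, k=1)
    inside |= d <= buf
    return inside.reshape(spec.nrows, spec.ncols)


# ---------------------------------------------------------------------------
# IDW
# ---------------------------------------------------------------------------

def idw_interpolate(samples: SampleTable, element: str, spec: GridSpec,
                    power: float = 2.0, k: int = 12,
                    mask: np.ndarray | None = None,
                    values: np.ndarray | None = None,
                    eps: float = 1e-9) -> Grid:
    """Inverse-distance-weighted surface from the k nearest samples.

    A cell whose center coincides with a sample (distance < ``eps``)
    takes that sample's value exactly. ``values`` overrides the element
    column (used to interpolate derived per-sample quantities such as
    contamination indices or PCA scores on the same geometry).
    """
    if power <= 0:
        raise ValidationError("IDW power must be positive")
    # sort by sample_id so k-th-neighbor ties resolve deterministically
    order = np.argsort(samples.sample_ids.astype(str), kind="stable")
    xy = samples.coords[order]
    z = (samples.conc(element) if values is None
         else np.asarray(values, dtype=float))[order]
    n = len(z)
    if k > n:
        raise ValidationError(f"k={k} neighbors requested but only {n} samples")
    if mask is None:
        mask = study_mask(spec, samples)

    xs, ys = spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = cKDTree(xy).query(pts, k=k)
    dist = np.atleast_2d(dist.reshape(len(pts), -1))
    idx = np.atleast_2d(idx.reshape(len(pts), -1))

    exact = dist[:, 0] < eps
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    est = (w * z[idx]).sum(axis=1) / np.where(w.sum(axis=1) > 0, w.sum(axis=1), 1.0)
    est[exact] = z[idx[exact, 0]]

    vals = est.reshape(spec.nrows, spec.ncols)
    vals = np.where(mask, vals, np.nan)
    return Grid(spec, vals, mask)


# ---------------------------------------------------------------------------
# Singularity analysis / MIDW
# ---------------------------------------------------------------------------

def _clipped_window_means(values: np.ndarray, mask: np.ndarray,
                          r: int) -> np.ndarray:
    """Mean over the (2r+1)×(2r+1) window centered at each cell, the
    window clipped at grid edges and masked cells excluded."""
    v = np.where(mask, values, 0.0)
    c = mask.astype(float)
    # integral images with a zero row/col prepended
    iv = np.zeros((v.shape[0] + 1, v.shape[1] + 1))
    ic = np.zeros_like(iv)
    iv[1:, 1:] = v.cumsum(0).cumsum(1)
    ic[1:, 1:] = c.cumsum(0).cumsum(1)
    nr, nc = v.shape
    i = np.arange(nr)[:, None]
    j = np.arange(nc)[None, :]
    r0 = np.clip(i - r, 0, nr); r1 = np.clip(i + r + 1, 0, nr)
    c0 = np.clip(j - r, 0, nc); c1 = np.clip(j + r + 1, 0, nc)
    s = iv[r1, c1] - iv[r0, c1] - iv[r1, c0] + iv[r0, c0]
    n = ic[r1, c1] - ic[r0, c1] - ic[r1, c0] + ic[r0, c0]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, s / n, np.nan)


def singularity_index(grid: Grid, window_halfwidths=(1, 2, 3, 4, 5),
                      alpha_bounds: tuple[float, float] = (0.5, 3.5),
                      ) -> tuple[Grid, Grid]:
    """Per-cell singularity exponent α and non-singular component c.

    Fits log μ = log c + (α−2)·log L by least squares, with L = 2r+1
    the window edge length in cells for each half-width r; c is thus
    the scaling law evaluated at the cell's own scale L = 1. α is
    clamped to ``alpha_bounds`` to stabilize edge cells.
    """
    radii = np.asarray(sorted(window_halfwidths), dtype=int)
    if len(radii) < 3:
        raise ValidationError("need at least 3 window sizes for the scaling fit")
    if len(np.unique(radii)) != len(radii):
        raise ValidationError("window half-widths must be distinct")
    if 2 * radii[-1] + 1 > max(grid.values.shape):
        raise ValidationError("largest window exceeds the grid")

    mus = np.stack([_clipped_window_means(grid.values, grid.mask, int(r))
                    for r in radii])                     # (R, nrows, ncols)
    tiny = np.nanmax(np.abs(grid.inside_values)) * 1e-12 + 1e-300
    logmu = np.log(np.clip(mus, tiny, None))
    logl = np.log(2.0 * radii + 1.0)[:, None, None]

    ll_mean = logl.mean()
    lm_mean = logmu.mean(axis=0)
    sxx = ((logl - ll_mean) ** 2).sum()
    sxy = ((logl - ll_mean) * (logmu - lm_mean)).sum(axis=0)
    slope = sxy / sxx
    intercept = lm_mean - slope * ll_mean

    alpha = np.clip(slope + 2.0, *alpha_bounds)
    # recompute c consistent with the clamped alpha at the mean log-L
    logc = lm_mean - (alpha - 2.0) * ll_mean
    cval = np.exp(logc)

    alpha = np.where(grid.mask, alpha, np.nan)
    cval = np.where(grid.mask, cval, np.nan)
    return (Grid(grid.spec, alpha, grid.mask),
            Grid(grid.spec, cval, grid.mask))


def midw_interpolate(samples: SampleTable, element: str, spec: GridSpec,
                     power: float = 2.0, k: int = 12,
                     window_halfwidths=(1, 2, 3, 4, 5),
                     mask: np.ndarray | None = None,
                     values: np.ndarray | None = None) -> Grid:
    """Multifractal IDW: IDW surface corrected by the local singularity,
    Z = c · L_min^(α−2) with L_min = 1 (the cell's own scale), i.e. the
    fitted non-singular component. Equals IDW wherever α = 2.

    The scaling fit needs a positive field; fields that take zero or
    negative values (index maps, component scores, balance coordinates)
    are shifted positive before the fit and shifted back afterwards, so
    the non-singular limit still reproduces the IDW surface exactly.
    """
    idw = idw_interpolate(samples, element, spec, power=power, k=k,
                          mask=mask, values=values)
    inside = idw.inside_values
    lo = float(inside.min()) if inside.size else 0.0
    shift = 0.0
    if lo <= 0:
        span = float(inside.max() - lo) if inside.size else 1.0
        shift = -lo + 0.05 * (span if span > 0 else 1.0)
    shifted = Grid(spec, np.where(idw.mask, idw.values + shift, np.nan),
                   idw.mask)
    alpha, c = singularity_index(shifted, window_halfwidths)
    vals = c.values - shift                 # c = scaling law at L_min = 1
    vals = np.where(idw.mask, vals, np.nan)
    return Grid(spec, vals, idw.mask)


# ---------------------------------------------------------------------------
# Class breaks
# ---------------------------------------------------------------------------

@dataclass
class ClassBreaks:
    """Ascending class thresholds plus fit diagnostics.

    ``thresholds`` has ``n_classes - 1`` entries; a value v falls in
    class i where thresholds[i-1] <= v < thresholds[i].
    """

    method: str
    thresholds: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly ascending")

    def classify(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.thresholds, np.asarray(values, float),
                               side="right")


def _segment_sse_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of the least-squares line over every index interval [i, j].

    Computed from prefix sums; entries with j < i+1 are +inf (segments
    need at least 2 points).
    """
    m = len(x)
    o = np.ones(m)
    c1 = np.concatenate([[0], np.cumsum(o)])
    cx = np.concatenate([[0], np.cumsum(x)])
    cy = np.concatenate([[0], np.cumsum(y)])
    cxx = np.concatenate([[0], np.cumsum(x * x)])
    cxy = np.concatenate([[0], np.cumsum(x * y)])
    cyy = np.concatenate([[0], np.cumsum(y * y)])

    i = np.arange(m)[:, None]
    j = np.arange(m)[None, :]
    n = c1[j + 1] - c1[i]
    sx = cx[j + 1] - cx[i]
    sy = cy[j + 1] - cy[i]
    sxx = cxx[j + 1] - cxx[i]
    sxy = cxy[j + 1] - cxy[i]
    syy = cyy[j + 1] - cyy[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / n
        cov = sxy - sx * sy / n
        vy = syy - sy * sy / n
        sse = vy - np.where(vx > 1e-12, cov * cov / np.where(vx > 0, vx, 1.0), 0.0)
    sse = np.where(j >= i + 1, np.maximum(sse, 0.0), np.inf)
    return sse


def _segmented_fit(x: np.ndarray, y: np.ndarray, n_segments: int
                   ) -> tuple[list[int], float]:
    """Optimal piecewise-linear fit with ``n_segments`` segments by
    dynamic programming; returns the start index of each segment after
    the first, and the total SSE."""
    m = len(x)
    if m < 2 * n_segments:
        raise ValidationError(
            f"{m} support points cannot carry {n_segments} 2-point segments")
    sse = _segment_sse_matrix(x, y)
    # dp[j] = best cost of fitting points [0..j] with `seg` segments
    dp = sse[0, :].copy()
    back: list[np.ndarray] = []
    for _ in range(1, n_segments):
        # row i-1 of cand = dp over [0..i-1] plus a new segment [i..j]
        cand = dp[None, :-1].T + sse[1:, :]          # rows i-1 = 0..m-2
        best = np.argmin(cand, axis=0)
        dp = cand[best, np.arange(m)]
        back.append(best + 1)                        # segment start index
    # recover breakpoints
    starts: list[int] = []
    jj = m - 1
    for layer in reversed(back):
        s = int(layer[jj])
        starts.append(s)
        jj = s - 1
    starts.reverse()
    return starts, float(dp[m - 1])


def ca_breaks(grid: Grid, n_classes: int = 4,
              max_support: int = 512) -> ClassBreaks:
    """Concentration–area fractal thresholds.

    A(s) counts unmasked cells with value ≥ s over the sorted unique
    values s. ``n_classes`` straight segments are fitted to the log–log
    curve by exact dynamic programming, with log s regressed on log A:
    in that orientation every statistical population contributes a
    bounded, comparable share of the objective, and the sparse
    concentration range between two populations shows up as a
    high-variance vertical run that attracts the breakpoint — a
    deterministic surrogate for picking the curve's marked inflexion
    points by eye. Each threshold is the geometric mean of the two
    concentrations flanking an optimal breakpoint. Requires strictly
    positive grid values (concentrations, indices).
    """
    vals = np.sort(grid.inside_values)
    vals = vals[vals > 0]  # the log–log curve exists for positive s only
    if vals.size == 0:
        raise ValidationError("C–A classification needs positive values")
    s = np.unique(vals)
    if len(s) < 2 * n_classes:
        raise ValidationError(
            f"only {len(s)} distinct values; cannot fit {n_classes} segments")
    area = len(vals) - np.searchsorted(vals, s, side="left")

    if len(s) > max_support:
        keep = np.unique(np.linspace(0, len(s) - 1, max_support).astype(int))
        s_fit, a_fit = s[keep], area[keep]
    else:
        s_fit, a_fit = s, area
    m = len(s_fit)

    # DP over the curve ordered by descending s (= ascending log A)
    x = np.log(a_fit.astype(float))[::-1].copy()
    y = np.log(s_fit)[::-1].copy()
    starts, total_sse = _segmented_fit(x, y, n_classes)
    # reversed breakpoint between r-1 and r ↔ ascending-s indices
    # m-1-r (lower flank) and m-r (upper flank)
    thresholds = np.sort([float(np.sqrt(s_fit[m - 1 - r] * s_fit[m - r]))
                          for r in starts])

    # per-segment diagnostics in conventional (log s, log A) orientation
    asc_bounds = sorted([0, *[m - r for r in starts], m])
    segs = []
    ls, la = np.log(s_fit), np.log(a_fit.astype(float))
    for a, b in zip(asc_bounds[:-1], asc_bounds[1:]):
        xs, ys = ls[a:b], la[a:b]
        if len(xs) < 2 or np.ptp(xs) == 0:
            slope, icpt = 0.0, float(ys.mean())
        else:
            slope, icpt = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + icpt)
        segs.append({"slope": float(slope), "intercept": float(icpt),
                     "sse": float((resid ** 2).sum())})
    diag = {"segments": segs, "total_sse": total_sse,
            "curve_s": s, "curve_area": area}
    return ClassBreaks("CA", thresholds, diag)


def jenks_breaks(values: np.ndarray, n_classes: int) -> ClassBreaks:
    """Jenks natural breaks by exact Fisher dynamic programming:
    class limits minimizing the total within-class sum of squared
    deviations."""
    v = np.sort(np.asarray(values, dtype=float))
    distinct = np.unique(v)
    if len(distinct) < n_classes:
        raise ValidationError(
            f"{len(distinct)} distinct values cannot form {n_classes} classes")
    n = len(v)
    cx = np.concatenate([[0], np.cumsum(v)])
    cxx = np.concatenate([[0], np.cumsum(v * v)])

    j_idx = np.arange(n)
    # dp over classes
    i_grid = np.arange(n)[:, None]
    nn = j_idx[None, :] - i_grid + 1
    s = cx[j_idx + 1][None, :] - cx[i_grid]
    s2 = cxx[j_idx + 1][None, :] - cxx[i_grid]
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_mat = np.where(nn >= 1, s2 - s * s / np.where(nn >= 1, nn, 1), np.inf)

    dp = ssd_mat[0, :].copy()
    back = []
    for _ in range(1, n_classes):
        cand = dp[None, :-1].T + ssd_mat[1:, :]
        best = np.argmin(cand, axis=0)
        dp = cand[best, np.arange(n)]
        back.append(best + 1)
    starts = []
    jj = n - 1
    for layer in reversed(back):
        stt = int(layer[jj])
        starts.append(stt)
        jj = stt - 1
    starts.reverse()
    thresholds = v[np.asarray(starts, dtype=int)]
    # strict ascent is guaranteed only across distinct class extremes
    thresholds = np.unique(thresholds)
    return ClassBreaks("jenks", thresholds,
                       {"gvf_sse": float(dp[n - 1]), "n": n})


def symmetric_score_breaks(values: np.ndarray,
                           q_frac: float = 0.25) -> ClassBreaks:
    """Breaks symmetric about 0 for component-score maps: scores near 0
    carry no information, so classes are ±q around it with
    q = ``q_frac`` · max|value|. All-positive or all-negative input
    falls back to quartile breaks with a warning."""
    v = np.asarray(values, dtype=float)
    if v.min() >= 0 or v.max() <= 0:
        warnings.warn("scores do not span 0; falling back to quantile breaks",
                      stacklevel=2)
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        qs = np.unique(qs)
        if len(qs) < 2:
            raise ValidationError("degenerate score vector")
        return ClassBreaks("quantile-fallback", qs)
    q = q_frac * np.abs(v).max()
    return ClassBreaks("symmetric", np.array([-q, 0.0, q]))
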