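"""Regime-shift detection and regime summaries for annual time series.

Four complementary views of the same question -- when did the mean state
of the system change:

* :func:`stars` -- Rodionov's sequential t-test analysis of regime shifts,
  applied per series.  A new regime is declared when a value leaves the
  current regime mean by more than a t-derived threshold and the regime
  shift index (RSI), a cumulative normalised and Huber-weighted excess over
  the following ``cutoff`` years, stays positive.
* :func:`pca_index` -- standardised PCA (correlation matrix) of ln(x+1)
  transformed series; PC1 of a forcing block is a pressure index, PC1 of a
  biomass block a state index.  :func:`stars_on_scores` chains the two.
* :func:`chronological_clustering` -- agglomerative clustering of years
  constrained to temporal contiguity; candidate fusions of adjacent year
  groups are accepted unless a permutation test rejects homogeneity, and
  refused fusions are the regime boundaries.
* :func:`traffic_light` -- per-variable quintile categories over time,
  rows ordered by PC1 loadings.

Plus per-regime coefficients of variation and anomaly series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "StarsConfig",
    "RegimeShiftResult",
    "PcaResult",
    "CcConfig",
    "Partition",
    "TrafficLightTable",
    "stars",
    "pca_index",
    "stars_on_scores",
    "chronological_clustering",
    "traffic_light",
    "coefficient_of_variation",
    "anomaly",
]


@dataclass
class StarsConfig:
    """Parameters of the sequential t-test: significance level ``alpha``,
    cut-off (minimum regime) length ``cutoff`` in years, and Huber weight
    parameter ``huber`` (outliers beyond ``huber`` standard deviations are
    down-weighted inversely to their distance)."""

    alpha: float = 0.05
    cutoff: int = 5
    huber: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cutoff < 2:
            raise ValueError("cutoff must be >= 2")
        if self.huber <= 0:
            raise ValueError("huber must be > 0")


@dataclass
class RegimeShiftResult:
    shift_years: list[int]
    rsi: dict[int, float]
    regime_bounds: list[tuple[int, int]]
    regime_means: list[float]  # Huber-weighted
    regime_means_raw: list[float]
    end_truncated: list[bool]  # per shift: confirmed only within the final cutoff years

    @property
    def confirmed_years(self) -> list[int]:
        """Shift years excluding those flagged as end-truncated."""
        return [y for y, t in zip(self.shift_years, self.end_truncated) if not t]


def _huber_mean(x: np.ndarray, sigma: float, h: float, iters: int = 3) -> float:
    """Huber-weighted mean: weights min(1, h/|z|) on anomalies beyond h SD."""
    m = float(np.mean(x))
    if sigma <= 0:
        return m
    for _ in range(iters):
        z = np.abs(x - m) / sigma
        w = np.minimum(1.0, h / np.maximum(z, 1e-12))
        m = float(np.sum(w * x) / np.sum(w))
    return m


def stars(
    series: pd.Series | np.ndarray,
    cfg: StarsConfig | None = None,
) -> RegimeShiftResult:
    """Rodionov's sequential t-test regime shift detection on one series.

    The detection threshold is ``diff = t_crit(alpha, 2l-2) * sqrt(2 s^2/l)``
    with ``s^2`` the variance averaged over all consecutive ``l``-year
    windows.  A value beyond the current regime mean +/- diff opens a
    candidate regime; it is confirmed iff the cumulative Huber-weighted RSI
    over the following ``l`` years never drops to zero.  Shifts that can
    only be confirmed within the final ``l`` years are reported but flagged
    ``end_truncated`` (their RSI uses fewer than ``l`` values).
    """
    cfg = cfg or StarsConfig()
    if isinstance(series, pd.Series):
        years = np.asarray(series.index, dtype=int)
        x = series.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
        years = np.arange(len(x))
    n = len(x)
    l = cfg.cutoff
    if n < 2 * l:
        raise ValueError(f"series of length {n} too short for cutoff {l} (need >= {2 * l})")
    if np.isnan(x).any():
        raise ValueError("series contains missing values")

    win_vars = np.array([np.var(x[i : i + l], ddof=1) for i in range(n - l + 1)])
    sigma2 = float(win_vars.mean())
    sigma = float(np.sqrt(sigma2))
    if sigma2 == 0.0:  # constant series: a single regime by definition
        return RegimeShiftResult(
            shift_years=[],
            rsi={},
            regime_bounds=[(int(years[0]), int(years[-1]))],
            regime_means=[float(x[0])],
            regime_means_raw=[float(np.mean(x))],
            end_truncated=[],
        )
    t_crit = stats.t.ppf(1 - cfg.alpha / 2, df=2 * l - 2)
    diff = t_crit * np.sqrt(2 * sigma2 / l)

    shifts: list[int] = []
    rsi_out: dict[int, float] = {}
    truncated: list[bool] = []
    starts = [0]
    cur_start = 0
    cur_mean = _huber_mean(x[:l], sigma, cfg.huber)

    i = l
    while i < n:
        xi = x[i]
        direction = 0
        if xi > cur_mean + diff:
            direction = 1
        elif xi < cur_mean - diff:
            direction = -1
        if direction == 0:
            cur_mean = _huber_mean(x[cur_start : i + 1], sigma, cfg.huber)
            i += 1
            continue
        level = cur_mean + direction * diff
        window = x[i : i + l]
        rsi = 0.0
        confirmed = True
        for xj in window:
            z = direction * (xj - level) / sigma if sigma > 0 else direction * (xj - level)
            w = 1.0 if abs(z) <= cfg.huber else cfg.huber / abs(z)
            rsi += w * z / l
            if rsi < 0:
                confirmed = False
                break
        if confirmed:
            shifts.append(i)
            rsi_out[int(years[i])] = rsi
            truncated.append(i + l > n)
            starts.append(i)
            cur_start = i
            cur_mean = _huber_mean(x[i : i + l], sigma, cfg.huber)
            i += 1
        else:
            cur_mean = _huber_mean(x[cur_start : i + 1], sigma, cfg.huber)
            i += 1

    bounds = []
    means_w = []
    means_raw = []
    edges = starts + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        bounds.append((int(years[a]), int(years[b - 1])))
        means_w.append(_huber_mean(x[a:b], sigma, cfg.huber))
        means_raw.append(float(np.mean(x[a:b])))
    return RegimeShiftResult(
        shift_years=[int(years[i]) for i in shifts],
        rsi=rsi_out,
        regime_bounds=bounds,
        regime_means=means_w,
        regime_means_raw=means_raw,
        end_truncated=truncated,
    )


# -- PCA ----------------------------------------------------------------------


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # years x components
    variance_explained: np.ndarray  # %, non-increasing


def _ln1p_signed(X: np.ndarray) -> np.ndarray:
    """Sign-preserving ln(1+|x|); equals ln(1+x) for non-negative data."""
    return np.sign(X) * np.log1p(np.abs(X))


def pca_index(
    matrix: pd.DataFrame,
    transform: bool = True,
    n_components: int | None = None,
) -> PcaResult:
    """Standardised PCA (correlation matrix) of ln(x+1)-transformed series.

    Negative values (anomaly series) are handled by the sign-preserving
    variant ln(1+|x|)*sign(x).  Each component is oriented so its
    largest-|loading| variable loads positively, making score plots
    reproducible.  Raises on zero-variance variables, naming them.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 years and 2 variables")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    if transform:
        X = _ln1p_signed(X)
    sd = X.std(axis=0, ddof=1)
    dead = [c for c, s in zip(matrix.columns, sd) if s <= 0]
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    Z = (X - X.mean(axis=0)) / sd
    k = n_components or min(Z.shape)
    p = PCA(n_components=k, svd_solver="full")
    scores = p.fit_transform(Z)
    load = p.components_.T  # variables x components
    # deterministic orientation
    for c in range(load.shape[1]):
        imax = int(np.argmax(np.abs(load[:, c])))
        if load[imax, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{c + 1}" for c in range(load.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(load, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        variance_explained=100.0 * p.explained_variance_ratio_,
    )


def stars_on_scores(
    pca: PcaResult, component: int = 1, cfg: StarsConfig | None = None
) -> RegimeShiftResult:
    """STARS applied to the scores of one principal component (1-based)."""
    col = f"PC{component}"
    return stars(pca.scores[col], cfg)


# -- chronological clustering -------------------------------------------------


@dataclass
class CcConfig:
    """alpha is the clustering-intensity level of the permutation test;
    ``connectedness`` the fraction of between-group links defining the
    fusion distance (0.5 = median linkage)."""

    alpha: float = 0.01
    connectedness: float = 0.5
    permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.connectedness <= 1:
            raise ValueError("connectedness must be in (0, 1]")


@dataclass
class Partition:
    """Contiguous segmentation of the year axis."""

    segments: list[tuple[int, int]]  # inclusive (start_year, end_year)
    boundary_years: list[int]  # first year of each segment after the first
    p_values: dict[int, float]  # boundary year -> permutation p of the refused fusion
    outliers: list[int]  # singleton years whose refused fusion marks them atypical


def _link_distance(D: np.ndarray, a: np.ndarray, b: np.ndarray, co: float) -> float:
    """Distance at which two groups connect once a fraction ``co`` of their
    between-group links is formed (co-quantile of cross distances)."""
    return float(np.quantile(D[np.ix_(a, b)].ravel(), co))


def _perm_pvalue(
    D: np.ndarray,
    pool: np.ndarray,
    n1: int,
    d_obs: float,
    co: float,
    nperm: int,
    rng: np.random.Generator,
) -> float:
    """Right-tail permutation p of the linkage distance under random
    re-assignment of the pooled years to the two group sizes."""
    m = len(pool)
    perms = rng.permuted(np.tile(pool, (nperm, 1)), axis=1)
    A, B = perms[:, :n1], perms[:, n1:]
    cross = D[A[:, :, None], B[:, None, :]].reshape(nperm, n1 * (m - n1))
    stats_ = np.quantile(cross, co, axis=1)
    return float((1 + np.sum(stats_ >= d_obs - 1e-12)) / (1 + nperm))


def chronological_clustering(
    matrix: pd.DataFrame, cfg: CcConfig | None = None
) -> Partition:
    """Temporally constrained agglomerative clustering with permutation tests.

    Variables are z-scored, years compared by Euclidean distance.  Only
    temporally adjacent groups may fuse; the candidate pair with the
    smallest linkage distance (at the connectedness level) is tested by
    permuting year memberships between the two groups: if the observed
    linkage distance is significantly large (p <= alpha) the fusion is
    refused and the boundary becomes permanent.  A refused fusion whose
    smaller side is a single year marks that year as an outlier instead of
    a boundary (the singleton is attached to its nearest neighbour group),
    following the original chronological-clustering prescription.  A
    refusal is not permanent: whenever either side's composition changes
    through later fusions the pair is tested again, so a boundary stands
    only if the rejection persists against the final neighbouring
    segments.  Deterministic given the config seed.
    """
    cfg = cfg or CcConfig()
    n = matrix.shape[0]
    if n < 4:
        raise ValueError("need at least 4 years")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    years = np.asarray(matrix.index, dtype=int)
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    D = squareform(pdist(Z))
    rng = np.random.default_rng(cfg.seed)

    clusters: list[np.ndarray] = [np.array([i]) for i in range(n)]
    # refused fusions keyed by the exact pair of compositions; re-tested if
    # either side changes
    refused: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    outliers: list[int] = []

    while True:
        candidates = []
        for ci in range(len(clusters) - 1):
            key = (tuple(clusters[ci]), tuple(clusters[ci + 1]))
            if key in refused:
                continue
            d = _link_distance(D, clusters[ci], clusters[ci + 1], cfg.connectedness)
            candidates.append((d, ci))
        if not candidates:
            break
        d_obs, ci = min(candidates)
        a, b = clusters[ci], clusters[ci + 1]
        pool = np.concatenate([a, b])
        m, n1 = len(pool), len(a)
        if m > 2:
            p = _perm_pvalue(D, pool, n1, d_obs, cfg.connectedness, cfg.permutations, rng)
        else:
            p = 1.0
        reject = p <= cfg.alpha
        if reject and min(n1, m - n1) == 1:
            # singleton refusal: atypical year, not a regime boundary
            single = int(a[0]) if n1 == 1 else int(b[0])
            if int(years[single]) not in outliers:
                outliers.append(int(years[single]))
            reject = False
        if reject:
            refused[(tuple(a), tuple(b))] = p
        else:
            clusters[ci : ci + 2] = [pool]

    pvals = {
        int(years[key[1][0]]): p
        for key, p in refused.items()
        if any(np.array_equal(np.asarray(key[1]), c) for c in clusters)
    }

    segments = [(int(years[c[0]]), int(years[c[-1]])) for c in clusters]
    boundaries = [int(years[c[0]]) for c in clusters[1:]]
    return Partition(
        segments=segments, boundary_years=boundaries, p_values=pvals, outliers=outliers
    )


# -- traffic-light table ------------------------------------------------------


@dataclass
class TrafficLightTable:
    """Quintile categories (1 lowest ... 5 highest) per variable and year,
    rows ordered by the supplied score (typically PC1 loadings), descending."""

    categories: pd.DataFrame  # variables x years, int 1..5
    order: list[str]

    #: category -> colour, green (low) through red (high)
    palette: dict[int, str] = field(
        default_factory=lambda: {
            1: "#1a9850",
            2: "#91cf60",
            3: "#ffffbf",
            4: "#fc8d59",
            5: "#d73027",
        }
    )

    def plot(self, ax=None):
        """Render the table as a coloured matrix (matplotlib axes)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        if ax is None:
            _, ax = plt.subplots(
                figsize=(0.28 * self.categories.shape[1] + 2, 0.3 * len(self.order) + 1)
            )
        cmap = ListedColormap([self.palette[k] for k in range(1, 6)])
        ax.imshow(self.categories.loc[self.order].to_numpy(), cmap=cmap, vmin=1, vmax=5, aspect="auto")
        ax.set_yticks(range(len(self.order)), self.order)
        cols = list(self.categories.columns)
        step = max(1, len(cols) // 12)
        ax.set_xticks(range(0, len(cols), step), cols[::step], rotation=90)
        return ax


def traffic_light(
    matrix: pd.DataFrame, ordering: pd.Series | dict | None = None
) -> TrafficLightTable:
    """Quintile-categorise each variable's time series (ties to the lower bin).

    ``matrix`` is years x variables; ``ordering`` maps variable -> score
    (rows are sorted by it, descending).  A constant variable is assigned
    the middle category with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    n = matrix.shape[0]
    cats = {}
    for var in matrix.columns:
        x = matrix[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant variable {var!r}: all cells set to category 3", stacklevel=2)
            cats[var] = np.full(n, 3, dtype=int)
            continue
        ranks = stats.rankdata(x, method="min")
        cats[var] = np.ceil(5.0 * ranks / n).astype(int)
    table = pd.DataFrame(cats, index=matrix.index).T
    if ordering is not None:
        s = pd.Series(ordering)
        order = list(s.loc[table.index].sort_values(ascending=False).index)
    else:
        order = list(table.index)
    return TrafficLightTable(categories=table.loc[order], order=order)


# -- regime summaries ---------------------------------------------------------


def coefficient_of_variation(
    series: pd.Series, periods: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Sample CV (SD with n-1 over |mean|) per closed year period.

    A period mean of zero yields NaN (explicit missing value).
    """
    out = {}
    years = np.asarray(series.index, dtype=int)
    for start, end in periods:
        if start < years.min() or end > years.max():
            raise ValueError(f"period {start}-{end} outside series span")
        seg = series.loc[(series.index >= start) & (series.index <= end)]
        m = float(seg.mean())
        out[(start, end)] = float(seg.std(ddof=1) / abs(m)) if m != 0 else np.nan
    return out


def anomaly(series: pd.Series, reference: str = "initial") -> pd.Series:
    """Series minus a reference: its first value (``"initial"``) or its mean."""
    if len(series) == 0:
        raise ValueError("empty series")
    if reference == "initial":
        ref = series.iloc[0]
    elif reference == "mean":
        ref = series.mean()
    else:
        raise ValueError("reference must be 'initial' or 'mean'")
    return series - ref
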