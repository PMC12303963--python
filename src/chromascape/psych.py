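"""Psychometric arm: healing-rating screening, semantic-differential
factor analysis, landscape clustering, and metric-factor correlation.

The workflow mirrors standard environmental-psychology practice:

1. a preliminary panel rates candidate photographs for perceived healing
   quality on a 7-point scale; images pass a consensus filter
   (mean >= 5.0, median >= 5.0, SD < 1.2);
2. participants rate the retained images on 24 bipolar semantic-
   differential items (5-point scale); principal-axis factoring with
   varimax rotation extracts the perceptual dimensions;
3. image-level factor scores are clustered with Ward's minimum-variance
   method to identify landscape types;
4. Pearson correlations link the per-color spatial metrics (D, H', C)
   to the perceptual factors.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "HealingRatingSummary",
    "FactorSolution",
    "ClusterSolution",
    "CorrelationTable",
    "summarize_healing_ratings",
    "select_samples",
    "item_correlation_matrix",
    "principal_axis_factor",
    "varimax_rotate",
    "screen_loadings",
    "factor_scores",
    "ward_cluster",
    "correlate_metrics_factors",
    "contribution_rates",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HealingRatingSummary:
    image_id: str
    n_raters: int
    mean: float
    median: float
    sd: float


@dataclasses.dataclass
class FactorSolution:
    """A factor solution over the semantic-differential items.

    ``eigenvalues`` are the per-factor sums of squared loadings; the
    contribution rate of factor j is 100 * eigenvalue_j / n_items and
    ``cumulative_pct`` is its running sum.  Communalities (row sums of
    squared loadings) are invariant under orthogonal rotation.
    """

    loadings: np.ndarray          # items x k
    eigenvalues: np.ndarray       # k
    contribution_rate_pct: np.ndarray
    cumulative_pct: np.ndarray
    communalities: np.ndarray     # items
    item_labels: list[str]
    rotation: np.ndarray | None = None
    converged: bool = True
    n_obs: int | None = None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1] if self.loadings.size else 0


@dataclasses.dataclass(frozen=True)
class ClusterSolution:
    assignments: dict[str, int]        # image id -> 1-based cluster id
    k: int
    merge_heights: np.ndarray
    mean_silhouette: float             # NaN when undefined (k == 1)
    profile: pd.DataFrame              # cluster x factor mean z-scores


@dataclasses.dataclass(frozen=True)
class CorrelationTable:
    """Metric x factor Pearson correlations with significance flags."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame  # "" / "*" (p<0.05) / "**" (p<0.01)

    def formatted(self) -> pd.DataFrame:
        out = self.r.copy().astype(object)
        for i in self.r.index:
            for c in self.r.columns:
                r = self.r.loc[i, c]
                out.loc[i, c] = ("NA" if np.isnan(r)
                                 else f"{r:.3f}{self.flags.loc[i, c]}")
        return out


# ---------------------------------------------------------------------------
# healing-quality screening

def summarize_healing_ratings(
    raw: Mapping[str, Sequence[int]],
) -> list[HealingRatingSummary]:
    """Per-image mean, median and sample SD of 7-point healing ratings.

    The median of an even-sized sample is the midpoint of the central
    pair; the SD uses the n-1 denominator (0 for a single rating).
    """
    out = []
    for image_id, ratings in raw.items():
        arr = np.asarray(list(ratings), dtype=float)
        if arr.size == 0:
            raise ValueError(f"image {image_id!r} has no ratings")
        if ((arr < 1) | (arr > 7) | (arr != np.round(arr))).any():
            raise ValueError(
                f"image {image_id!r}: ratings must be integers in 1..7")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(HealingRatingSummary(
            image_id=str(image_id), n_raters=int(arr.size),
            mean=float(arr.mean()), median=float(np.median(arr)), sd=sd))
    return out


def select_samples(summaries: Sequence[HealingRatingSummary],
                   mean_min: float = 5.0, median_min: float = 5.0,
                   sd_max: float = 1.2) -> list[str]:
    """Consensus filter: mean and median at or above the floor (inclusive),
    SD strictly below the ceiling."""
    return [s.image_id for s in summaries
            if s.mean >= mean_min and s.median >= median_min
            and s.sd < sd_max]


# ---------------------------------------------------------------------------
# factor analysis

def item_correlation_matrix(data: np.ndarray | pd.DataFrame,
                            item_labels: Sequence[str] | None = None,
                            ) -> pd.DataFrame:
    """Pearson correlation matrix of the items over observation rows.

    ``data`` is observations x items (e.g. participant-by-image rows).
    A zero-variance item is a hard error naming the item — it cannot be
    correlated and would silently poison the factoring.
    """
    if isinstance(data, pd.DataFrame):
        if item_labels is None:
            item_labels = list(data.columns)
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 observations")
    if item_labels is None:
        item_labels = [f"item{i + 1}" for i in range(data.shape[1])]
    sd = data.std(axis=0)
    dead = [item_labels[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance item(s): {dead}")
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=list(item_labels),
                        columns=list(item_labels))


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (initial communality estimates)."""
    try:
        inv = np.linalg.inv(corr)
        smc = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(corr)
        with np.errstate(divide="ignore"):
            smc = 1.0 - 1.0 / np.diag(inv)
    return np.clip(smc, 0.0, 1.0)


def kaiser_n_factors(corr: np.ndarray | pd.DataFrame) -> int:
    """Number of eigenvalues of the (unreduced) correlation matrix that
    strictly exceed 1.0."""
    corr = np.asarray(corr, dtype=float)
    eig = np.linalg.eigvalsh(corr)
    return int((eig > 1.0).sum())


def principal_axis_factor(corr: np.ndarray | pd.DataFrame,
                          n_factors: int | None = None,
                          item_labels: Sequence[str] | None = None,
                          tol: float = 1e-6, max_iter: int = 100,
                          ) -> FactorSolution:
    """Principal-axis factoring with iterated communalities.

    Communalities start at the squared multiple correlations and are
    iterated on the reduced correlation matrix until they change by less
    than ``tol`` (or ``max_iter`` is hit, flagged via ``converged``).
    With ``n_factors=None`` the Kaiser rule (eigenvalue > 1.0 of the
    unreduced matrix) sets the number of factors; zero retained factors
    yields an explicit empty solution.  Heywood cases (communality
    reaching 1) are clamped with a warning.
    """
    if isinstance(corr, pd.DataFrame):
        if item_labels is None:
            item_labels = list(corr.columns)
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("corr must be a symmetric square matrix")
    if item_labels is None:
        item_labels = [f"item{i + 1}" for i in range(p)]

    if n_factors is None:
        n_factors = kaiser_n_factors(corr)
    if n_factors == 0:
        empty = np.zeros((p, 0))
        return FactorSolution(
            loadings=empty, eigenvalues=np.zeros(0),
            contribution_rate_pct=np.zeros(0), cumulative_pct=np.zeros(0),
            communalities=np.zeros(p), item_labels=list(item_labels))
    if n_factors > p:
        raise ValueError(f"cannot extract {n_factors} factors from {p} items")

    h2 = _smc(corr)
    converged = False
    loadings = np.zeros((p, n_factors))
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        eigval, eigvec = np.linalg.eigh(reduced)
        order = np.argsort(eigval)[::-1][:n_factors]
        lam = np.clip(eigval[order], 0.0, None)
        loadings = eigvec[:, order] * np.sqrt(lam)
        new_h2 = (loadings ** 2).sum(axis=1)
        if (new_h2 > 1.0).any():
            warnings.warn("Heywood case: communality > 1 clamped to 1",
                          RuntimeWarning, stacklevel=2)
            new_h2 = np.minimum(new_h2, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            converged = True
            break
        h2 = new_h2
    if not converged:
        logger.warning("principal-axis iteration did not converge in "
                       "%d iterations; returning last iterate", max_iter)

    eigenvalues = (loadings ** 2).sum(axis=0)
    contrib, cumulative = contribution_rates(eigenvalues, p)
    return FactorSolution(
        loadings=loadings, eigenvalues=eigenvalues,
        contribution_rate_pct=contrib, cumulative_pct=cumulative,
        communalities=h2, item_labels=list(item_labels),
        converged=converged)


def contribution_rates(eigenvalues: Sequence[float], n_items: int,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor variance contribution (% of total item variance) and
    its running cumulative sum: 100 * eigenvalue_j / n_items."""
    ev = np.asarray(eigenvalues, dtype=float)
    contrib = 100.0 * ev / n_items
    return contrib, np.cumsum(contrib)


def printed_contribution_rates(eigenvalues: Sequence[float | str],
                               n_items: int, ndigits: int = 3,
                               ) -> tuple[list[float], list[float]]:
    """Contribution rates in printed-table form: exact decimal arithmetic
    with half-up rounding to ``ndigits`` places.

    Published factor tables round fixed-point half-up; binary floats
    round 64.3125 down to 64.312, so the running sums here are carried
    in :class:`decimal.Decimal` and only rounded for display.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    ev = [Decimal(str(e)) for e in eigenvalues]
    contrib = [e * 100 / Decimal(n_items) for e in ev]
    cum, running = [], Decimal(0)
    for c in contrib:
        running += c
        cum.append(running)
    rounded = lambda xs: [float(x.quantize(q, rounding=ROUND_HALF_UP))
                          for x in xs]
    return rounded(contrib), rounded(cum)


def varimax_rotate(loadings: np.ndarray, tol: float = 1e-6,
                   max_iter: int = 500,
                   kaiser_normalize: bool = True,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax rotation.

    Returns (rotated loadings, rotation matrix T) with ``rotated =
    loadings @ T`` and T orthonormal.  Columns are reordered by explained
    variance (descending) and sign-fixed so each column's largest-
    magnitude loading is positive.  A single factor is returned as-is
    (identity rotation).  Communalities are preserved exactly up to
    floating point.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)

    h = np.sqrt((A ** 2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    L = A / h_safe[:, None] if kaiser_normalize else A.copy()

    # Kaiser's pairwise planar rotations: for each column pair the
    # criterion-maximizing angle has a closed form, so sweeps cannot
    # stall on symmetric (saddle-point) configurations.
    B = L.copy()
    T = np.eye(k)
    for _ in range(max_iter):
        total_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / p
                den = ((u ** 2 - v ** 2).sum()
                       - (u.sum() ** 2 - v.sum() ** 2) / p)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                B[:, [i, j]] = B[:, [i, j]] @ rot
                T[:, [i, j]] = T[:, [i, j]] @ rot
                total_angle += abs(phi)
        if total_angle < tol:
            break

    rotated = B
    if kaiser_normalize:
        rotated = rotated * h_safe[:, None]

    # order columns by explained variance, then fix signs
    order = np.argsort(-(rotated ** 2).sum(axis=0), kind="stable")
    rotated = rotated[:, order]
    T = T[:, order]
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0),
                            np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    T *= signs
    return rotated, T


def rotate_solution(solution: FactorSolution) -> FactorSolution:
    """Varimax-rotate a factor solution, recomputing per-factor variance
    shares; communalities are untouched by the orthogonal rotation."""
    if solution.n_factors < 2:
        return solution
    rotated, T = varimax_rotate(solution.loadings)
    eigenvalues = (rotated ** 2).sum(axis=0)
    contrib, cumulative = contribution_rates(eigenvalues,
                                             solution.loadings.shape[0])
    return FactorSolution(
        loadings=rotated, eigenvalues=eigenvalues,
        contribution_rate_pct=contrib, cumulative_pct=cumulative,
        communalities=solution.communalities,
        item_labels=solution.item_labels, rotation=T,
        converged=solution.converged, n_obs=solution.n_obs)


def screen_loadings(solution: FactorSolution, load_min: float = 0.40,
                    crossload_gap: float = 0.20,
                    ) -> tuple[list[str], dict[str, int]]:
    """Simple-structure screen on a rotated solution.

    An item is dropped when its largest absolute loading is below
    ``load_min`` or when the gap to its second-largest absolute loading
    is below ``crossload_gap`` (a cross-loader).  Survivors are assigned
    to their max-loading factor (0-based index).
    """
    retained: list[str] = []
    assignment: dict[str, int] = {}
    absL = np.abs(solution.loadings)
    for i, label in enumerate(solution.item_labels):
        row = absL[i]
        if row.size == 0:
            continue
        top = float(row.max())
        second = float(np.sort(row)[-2]) if row.size > 1 else 0.0
        if top < load_min or (top - second) < crossload_gap:
            continue
        retained.append(label)
        assignment[label] = int(row.argmax())
    return retained, assignment


def factor_scores(data: np.ndarray | pd.DataFrame,
                  solution: FactorSolution,
                  method: str = "regression") -> np.ndarray:
    """Factor scores for observation rows (Thurstone regression method).

    Items are standardized over observations, then scores are
    ``Z R^-1 L`` (regression) or the Bartlett weighted-least-squares
    variant.  A singular item correlation matrix falls back to a ridge
    inverse (1e-8 on the diagonal) with a warning.
    """
    if solution.n_factors < 1:
        raise ValueError("cannot score an empty factor solution")
    X = np.asarray(data, dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = np.corrcoef(X, rowvar=False)
    L = solution.loadings
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        logger.warning("singular item correlation matrix; using ridge "
                       "inverse (1e-8)")
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(R.shape[0]))

    if method == "regression":
        W = Rinv @ L
    elif method == "bartlett":
        u2 = np.clip(1.0 - solution.communalities, 1e-8, None)
        Psi_inv = np.diag(1.0 / u2)
        W = Psi_inv @ L @ np.linalg.inv(L.T @ Psi_inv @ L)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return Z @ W


def image_factor_scores(scores: np.ndarray, image_ids: Sequence[str],
                        ) -> pd.DataFrame:
    """Average observation-level factor scores per image, then z-score
    each factor across images (the clustering input)."""
    df = pd.DataFrame(scores)
    df["image_id"] = list(image_ids)
    means = df.groupby("image_id", sort=False).mean()
    z = (means - means.mean()) / means.std(ddof=1)
    z.columns = [f"factor{j + 1}" for j in range(z.shape[1])]
    return z


# ---------------------------------------------------------------------------
# clustering

def ward_cluster(image_scores: pd.DataFrame, k: int | None = 8,
                 k_range: tuple[int, int] = (2, 10)) -> ClusterSolution:
    """Ward minimum-variance clustering of image factor scores.

    Agglomeration uses squared-Euclidean increase in within-cluster sum
    of squares (the classic Ward criterion).  ``k=None`` picks the k in
    ``k_range`` that maximizes the mean silhouette width.  Per-cluster
    mean z-scores are reported as the landscape-type profile.
    """
    X = image_scores.to_numpy(dtype=float)
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("factor scores must be finite")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of images ({n})")

    Z = linkage(X, method="ward")
    if k is None:
        best_k, best_sil = None, -np.inf
        for kk in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(X, labels)
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k if best_k is not None else 2
    labels = fcluster(Z, t=k, criterion="maxclust")

    n_found = len(np.unique(labels))
    if 2 <= n_found <= n - 1:
        sil = float(silhouette_score(X, labels))
    else:
        sil = float("nan")  # silhouette undefined for k=1 or k=n

    profile = (pd.DataFrame(X, columns=image_scores.columns,
                            index=image_scores.index)
               .groupby(pd.Series(labels, index=image_scores.index))
               .mean())
    profile.index.name = "cluster"
    return ClusterSolution(
        assignments={img: int(lab) for img, lab
                     in zip(image_scores.index, labels)},
        k=int(k), merge_heights=Z[:, 2].copy(),
        mean_silhouette=sil, profile=profile)


# ---------------------------------------------------------------------------
# metric-factor correlation

def correlate_metrics_factors(metrics: pd.DataFrame,
                              factors: pd.DataFrame,
                              min_pairs: int = 4) -> CorrelationTable:
    """Pearson correlations between color metrics and factor scores.

    ``metrics``: images x 18 metric columns (may contain NaN for
    undefined metrics); ``factors``: images x k factor-score columns.
    Each cell uses pairwise-complete observations; p-values come from
    the t distribution with n-2 df; flags mark p < 0.05 (*) and
    p < 0.01 (**).  Constant or too-sparse columns yield NaN cells with
    a warning.
    """
    common = metrics.index.intersection(factors.index)
    if len(common) < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} common images, have {len(common)}")
    M = metrics.loc[common]
    F = factors.loc[common]

    r = pd.DataFrame(index=M.columns, columns=F.columns, dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=M.columns, columns=F.columns, dtype=float)
    flags = pd.DataFrame("", index=M.columns, columns=F.columns)
    for mcol in M.columns:
        for fcol in F.columns:
            x = M[mcol].to_numpy(dtype=float)
            y = F[fcol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n.loc[mcol, fcol] = int(ok.sum())
            if ok.sum() < min_pairs or x[ok].std() == 0 or y[ok].std() == 0:
                logger.warning("correlation undefined for %s x %s "
                               "(constant or too few pairs)", mcol, fcol)
                r.loc[mcol, fcol] = np.nan
                p.loc[mcol, fcol] = np.nan
                flags.loc[mcol, fcol] = "NA"
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r.loc[mcol, fcol] = res.statistic
            p.loc[mcol, fcol] = res.pvalue
            flags.loc[mcol, fcol] = ("**" if res.pvalue < 0.01
                                     else "*" if res.pvalue < 0.05 else "")
    return CorrelationTable(r=r, p=p, n=n, flags=flags)
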