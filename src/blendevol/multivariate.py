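"""Blend dissimilarity, ordination and descriptive statistics.

Euclidean distances between blend profiles (optionally log(x+1)
transformed), Kruskal non-metric multidimensional scaling on five axes,
within-species dissimilarity and dispersion around the species' geometric
median, per-species compound counts, Welch two-sample t-tests, and a
permutational multivariate ANOVA (PERMANOVA) on the distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .alignment import BlendMatrix
from .io_peaktables import DegenerateStatisticError, ValidationError

logger = logging.getLogger("blendevol")

TRANSFORMS = ("none", "log_plus_one")


def apply_transform(X: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return np.asarray(X, dtype=float)
    if transform == "log_plus_one":
        return np.log1p(np.asarray(X, dtype=float))
    raise ValidationError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with row labels."""

    labels: list[str]
    values: np.ndarray
    transform: str = "none"

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if np.isnan(D).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if (D < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        self.values = D

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.transform)


def euclidean_distances(
    matrix: BlendMatrix | pd.DataFrame, transform: str = "log_plus_one"
) -> DistanceMatrix:
    """Euclidean distances between rows after the configured transform."""
    df = matrix.data if isinstance(matrix, BlendMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("blend matrix contains NaN cells")
    Xt = apply_transform(X, transform)
    D = squareform(pdist(Xt, metric="euclidean"))
    return DistanceMatrix(labels=[str(i) for i in df.index], values=D, transform=transform)


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling (Kruskal stress-1)

@dataclass
class OrdinationResult:
    configuration: pd.DataFrame  # points x k axes
    stress: float
    n_restarts: int
    seed: int | None
    converged: bool
    stress_trace: list[float]


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(d_config**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_config - disparities) ** 2) / denom))


def _nmds_single(
    D: np.ndarray, k: int, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    n = D.shape[0]
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")  # primary (weak-tie) approach
    X = X0.copy()
    trace: list[float] = []
    best_X, best_stress = X.copy(), np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        # monotone (isotonic) regression of configuration distances on the
        # rank order of the input dissimilarities
        disp = np.empty_like(d)
        disp[order] = isotonic_regression(d[order]).x
        # scale disparities to the size of the current configuration
        ssd = np.sum(disp**2)
        if ssd > 0:
            disp *= np.sqrt(np.sum(d**2) / ssd)
        stress = _stress1(d, disp)
        if stress > best_stress + 1e-15:
            break  # keep the monotone prefix of the trace
        improvement = best_stress - stress
        best_stress = stress
        best_X = X.copy()
        trace.append(stress)
        if stress < 1e-12 or improvement < tol:
            converged = True
            break
        # Guttman transform with the disparities as target distances
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, disp / d, 0.0)
        B = -squareform(ratio, checks=False)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B.dot(X) / n
    return best_X, best_stress, converged, trace


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(
    D: DistanceMatrix,
    k: int = 5,
    seed: int | None = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Kruskal non-metric MDS of a distance matrix into ``k`` axes.

    The first start is the classical-scaling (principal coordinates)
    configuration; remaining restarts are random. Each start alternates
    isotonic regression of configuration distances on the dissimilarity
    rank order with a Guttman configuration update, keeping the monotone
    stress-1 trace; the best (lowest-stress) solution over starts is
    returned. Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    n = D.n
    if k >= n:
        raise ValidationError(f"k = {k} must be smaller than the number of points {n}")
    rng = np.random.default_rng(seed)
    starts = [_classical_mds(D.values, k)]
    scale = D.values.max() or 1.0
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.normal(scale=scale, size=(n, k)))
    best = None
    for X0 in starts:
        X, stress, converged, trace = _nmds_single(D.values, k, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, converged, trace)
    X, stress, converged, trace = best
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    config = pd.DataFrame(
        X, index=pd.Index(D.labels, name="label"),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        configuration=config, stress=stress, n_restarts=len(starts),
        seed=seed, converged=converged, stress_trace=trace,
    )


# ---------------------------------------------------------------------------
# within-species statistics

def within_species_distance(D: DistanceMatrix, meta: pd.DataFrame) -> pd.Series:
    """Mean pairwise distance between conspecific samples, per species.

    Species represented by a single sample carry no pairwise information
    and are excluded (logged).
    """
    species = meta.loc[D.labels, "species"]
    out = {}
    for sp, grp in species.groupby(species):
        ids = list(grp.index)
        if len(ids) < 2:
            logger.info("species %s has a single sample; excluded", sp)
            continue
        sub = D.submatrix(ids).values
        iu = np.triu_indices(len(ids), k=1)
        out[sp] = float(sub[iu].mean())
    return pd.Series(out, name="within_species_distance").rename_axis("species")


def compounds_per_species(
    matrix: BlendMatrix, meta: pd.DataFrame, mode: str = "per_individual_mean"
) -> pd.Series:
    """Number of distinct compounds per species.

    ``per_individual_mean`` averages each conspecific sample's count of
    detected (nonzero) compounds; ``species_union`` counts compounds
    detected in at least one conspecific sample.
    """
    if mode not in ("per_individual_mean", "species_union"):
        raise ValidationError(f"unknown mode {mode!r}")
    detected = matrix.data > 0
    species = meta.loc[detected.index, "species"]
    if mode == "per_individual_mean":
        counts = detected.sum(axis=1).groupby(species.to_numpy()).mean()
    else:
        counts = detected.groupby(species.to_numpy()).any().sum(axis=1).astype(float)
    counts.name = f"n_compounds[{mode}]"
    return counts.rename_axis("species")


# ---------------------------------------------------------------------------
# dispersion around the group geometric median

def geometric_median(
    X: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000
) -> np.ndarray:
    """Weiszfeld iteration for the spatial median of rows of ``X``.

    For two points the minimizer is any point on the connecting segment;
    the midpoint is returned by convention. Iterates landing on a data
    point are perturbed off it (standard coincident-point guard).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 1:
        return X[0].copy()
    if n == 2:
        return X.mean(axis=0)
    y = X.mean(axis=0)
    eps = 1e-14
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        on_point = d < eps
        others = ~on_point
        if not others.any():
            return y  # all points coincide
        w = 1.0 / d[others]
        T = (X[others] * w[:, None]).sum(axis=0) / w.sum()
        if not on_point.any():
            y_next = T
        else:
            # Vardi-Zhang step when the iterate sits on a data point
            R = ((X[others] - y) * w[:, None]).sum(axis=0)
            r = np.linalg.norm(R)
            n_coincident = int(on_point.sum())
            if r <= n_coincident:
                return y  # the data point itself is the median
            y_next = max(0.0, 1.0 - n_coincident / r) * T + min(
                1.0, n_coincident / r
            ) * y
        if np.linalg.norm(y_next - y) < tol:
            return y_next
        y = y_next
    logger.warning("Weiszfeld iteration hit max_iter without tol convergence")
    return y


@dataclass
class DispersionResult:
    medians: pd.DataFrame  # group x coordinates
    sample_distances: pd.Series  # per sample, distance to own group median
    group_dispersion: pd.Series  # per group, mean member distance
    excluded_groups: list[str]


def dispersion(points: pd.DataFrame, groups: pd.Series) -> DispersionResult:
    """Distance of each member from its group's geometric median.

    ``points`` are sample coordinates (blend-matrix rows or ordination
    axes); ``groups`` maps each row to a group (typically the species).
    Groups with fewer than two members are excluded (logged).
    """
    groups = groups.loc[points.index]
    medians, dists, excluded = {}, {}, []
    for g, grp in points.groupby(groups.to_numpy()):
        if len(grp) < 2:
            excluded.append(str(g))
            logger.info("group %s has a single member; excluded from dispersion", g)
            continue
        m = geometric_median(grp.to_numpy())
        medians[g] = m
        for sid, row in zip(grp.index, grp.to_numpy()):
            dists[sid] = float(np.linalg.norm(row - m))
    med_df = pd.DataFrame(medians).T
    med_df.columns = points.columns
    sample_d = pd.Series(dists, name="distance_to_median")
    group_d = sample_d.groupby(groups.loc[sample_d.index].to_numpy()).mean()
    group_d.name = "mean_dispersion"
    return DispersionResult(
        medians=med_df, sample_distances=sample_d,
        group_dispersion=group_d.rename_axis("group"), excluded_groups=excluded,
    )


# ---------------------------------------------------------------------------
# Welch two-sample t-test

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y), with
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch test needs at least two values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateStatisticError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(np.sqrt(vx)), sd_y=float(np.sqrt(vy)),
        n_x=len(x), n_y=len(y),
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    seed: int | None


def _ss_within(D2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        ss += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(
    D: DistanceMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums the analogous
    per-group quantities; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    The p-value is (b+1)/(m+1) over ``n_perm`` random label permutations
    with the given seed.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    n = D.n
    if len(labels) != n:
        raise ValidationError("labels length does not match distance matrix")
    groups = labels.unique()
    a = len(groups)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if n <= a:
        raise ValidationError("PERMANOVA needs more samples than groups")
    D2 = D.values**2
    if not D2.any():
        raise DegenerateStatisticError("all distances are zero; F undefined")
    iu = np.triu_indices(n, k=1)
    ss_total = float(D2[iu].sum()) / n
    group_idx = [np.flatnonzero(labels.to_numpy() == g) for g in groups]
    ss_within = _ss_within(D2, group_idx)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    if ss_within <= 1e-300:
        f_obs = np.inf
    else:
        f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    sizes = [len(idx) for idx in group_idx]
    count = 0
    chunk = max(1, min(n_perm, int(2e7 / (max(sizes) ** 2 + 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        ssw = np.zeros(m)
        start = 0
        for idx in group_idx:
            cols = perms[:, start:start + len(idx)]
            ssw += D2[cols[:, :, None], cols[:, None, :]].sum(axis=(1, 2)) / (
                2 * len(idx)
            )
            start += len(idx)
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ssb / df_b) / (ssw / df_w)
        f_perm = np.where(ssw <= 1e-300, np.inf, f_perm)
        count += int(np.sum(f_perm >= f_obs))
        done += m
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        ss_total=ss_total, ss_between=ss_between, ss_within=ss_within,
        df_between=df_b, df_within=df_w, pseudo_f=float(f_obs), r2=float(r2),
        p=float(p), n_perm=n_perm, seed=seed,
    )
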