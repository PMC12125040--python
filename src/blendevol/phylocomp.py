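"""Comparative-phylogenetic statistics for multivariate blend traits.

Machinery for trait evolution under Brownian motion (BM) on a rooted,
branch-length-calibrated phylogeny: the tip covariance matrix from shared
branch lengths, the generalized-least-squares ancestral mean, multivariate
phylogenetic signal (K_mult, the multivariate generalization of Blomberg's
K, ~1 under BM), net evolutionary-rate (sigma^2_mult) comparison between
clades, and maximum-likelihood single-rate and clade-rate-shift BM models
on ordination axes with a simulation-based cutoff for declaring a shift.

All stochastic procedures (permutations, null simulations) take explicit
seeds and report them in their result records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

from .alignment import BlendMatrix
from .io_peaktables import DegenerateStatisticError, ValidationError
from .multivariate import apply_transform

logger = logging.getLogger("blendevol")

_RIDGE = 1e-10


class Phylogeny:
    """Rooted phylogeny with branch lengths in Myr, tips labelled by species.

    Wraps a dendropy tree; internal nodes get stable preorder identifiers
    ``n0`` (root), ``n1``, ... used to address clades in rate-shift fits.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")
        self.tip_labels: list[str] = sorted(labels)
        self._index: dict[str, int] = {l: i for i, l in enumerate(self.tip_labels)}
        self._depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            length = node.edge.length or 0.0
            self._depths[node] = (self._depths[parent] if parent else 0.0) + length
        self._node_ids: dict[str, dendropy.Node] = {}
        for k, node in enumerate(
            n for n in tree.preorder_node_iter() if not n.is_leaf()
        ):
            self._node_ids[f"n{k}"] = node

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "Phylogeny":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **kwargs
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def internal_node_ids(self) -> list[str]:
        return list(self._node_ids)

    @property
    def root_id(self) -> str:
        return "n0"

    def node(self, node_id: str) -> dendropy.Node:
        try:
            return self._node_ids[node_id]
        except KeyError:
            raise ValidationError(f"unknown internal node id {node_id!r}") from None

    def clade_tips(self, node_id: str) -> list[str]:
        node = self.node(node_id)
        return sorted(lf.taxon.label for lf in node.leaf_iter())

    def depth(self, node) -> float:
        return self._depths[node]

    def covariance(self) -> np.ndarray:
        """BM tip covariance: C_ij = depth of MRCA(i, j); C_ii = tip depth."""
        n = self.n_tips
        C = np.zeros((n, n))
        below: dict[dendropy.Node, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = self._index[node.taxon.label]
                C[i, i] = self._depths[node]
                below[node] = [i]
            else:
                children = [below[ch] for ch in node.child_nodes()]
                d = self._depths[node]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = d
                below[node] = [i for ch in children for i in ch]
        return C

    def subtree(self, labels) -> "Phylogeny":
        """Subtree induced by the given tip labels (branch lengths preserved)."""
        labels = list(labels)
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise ValidationError(f"labels not in tree: {missing}")
        pruned = self.tree.extract_tree_with_taxa_labels(labels)
        return Phylogeny(pruned)

    def shift_component(self, node_id: str) -> np.ndarray:
        """Covariance contribution of the clade's scaled edges.

        A rate multiplier r at ``node_id`` scales the node's stem edge and
        every edge of its subtree, so the tip covariance becomes
        C + (r - 1) * M with M_ij = C_ij - depth(parent(node)) for tip pairs
        inside the clade and 0 elsewhere.
        """
        node = self.node(node_id)
        if node.parent_node is None:
            raise ValidationError(
                "a shift at the root is indistinguishable from the global rate"
            )
        C = self.covariance()
        tips = [self._index[l] for l in self.clade_tips(node_id)]
        d_above = self._depths[node.parent_node]
        M = np.zeros_like(C)
        idx = np.ix_(tips, tips)
        M[idx] = C[idx] - d_above
        return M


def load_tree(path) -> Phylogeny:
    return Phylogeny.from_newick(str(path), is_path=True)


def phylo_cov(phylo: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """BM tip covariance matrix and its (sorted) tip-label order."""
    return phylo.covariance(), list(phylo.tip_labels)


# ---------------------------------------------------------------------------
# GLS helpers

def _safe_cho_factor(C: np.ndarray):
    try:
        return sla.cho_factor(C, lower=True)
    except sla.LinAlgError:
        logger.warning("covariance numerically singular; adding ridge %g", _RIDGE)
        return sla.cho_factor(C + _RIDGE * np.eye(len(C)), lower=True)


def phylogenetic_mean(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """GLS estimate of the ancestral (root) mean: a = (1'C^-1 1)^-1 1'C^-1 Y."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and C.shape[0] != 1:
        Y = Y.T
    cho = _safe_cho_factor(np.asarray(C, dtype=float))
    ones = np.ones(C.shape[0])
    w = sla.cho_solve(cho, ones)
    return w @ Y / (ones @ w)


def _align_traits(Y: pd.DataFrame | np.ndarray, phylo: Phylogeny) -> np.ndarray:
    if isinstance(Y, pd.DataFrame):
        missing = [l for l in phylo.tip_labels if l not in Y.index]
        if missing:
            raise ValidationError(f"traits missing for tips: {missing}")
        return Y.loc[phylo.tip_labels].to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != phylo.n_tips:
        raise ValidationError("trait rows do not match number of tips")
    return Y


def trait_matrix_from_blend(
    matrix: BlendMatrix, meta: pd.DataFrame, transform: str = "log_plus_one"
) -> pd.DataFrame:
    """Species-mean transformed relative amounts (species x compounds)."""
    X = apply_transform(matrix.data.to_numpy(), transform)
    df = pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns)
    species = meta.loc[df.index, "species"]
    return df.groupby(species.to_numpy()).mean().rename_axis("species")


# ---------------------------------------------------------------------------
# multivariate phylogenetic signal

@dataclass
class KmultResult:
    k_mult: float
    p: float
    n_perm: int
    seed: int | None
    n_tips: int
    n_traits: int


def _kmult_stat(Y: np.ndarray, Cinv: np.ndarray, expect: float) -> float:
    ones = np.ones(Y.shape[0])
    w = Cinv @ ones
    a = w @ Y / (ones @ w)
    E = Y - a
    num = float(np.sum(E * E))
    den = float(np.sum(E * (Cinv @ E)))
    if num == 0.0 or den == 0.0:
        raise DegenerateStatisticError("constant traits: K_mult undefined")
    return (num / den) / expect


def kmult(
    Y: pd.DataFrame | np.ndarray,
    phylo: Phylogeny,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> KmultResult:
    """Multivariate phylogenetic signal K_mult.

    K_mult = [tr(E'E) / tr(E'C^-1 E)] * (N-1) / (tr(C) - N/(1'C^-1 1)),
    with E the tip deviations from the GLS ancestral mean. Equals 1 in
    expectation under BM on the given tree (and exactly 1 on a star tree);
    values near 0 indicate no phylogenetic structure. Significance by
    permuting trait rows across tips.
    """
    Ym = _align_traits(Y, phylo)
    N = Ym.shape[0]
    if N < 4:
        raise ValidationError("K_mult needs at least 4 tips")
    C = phylo.covariance()
    cho = _safe_cho_factor(C)
    Cinv = sla.cho_solve(cho, np.eye(N))
    ones = np.ones(N)
    expect = (np.trace(C) - N / (ones @ Cinv @ ones)) / (N - 1)
    k_obs = _kmult_stat(Ym, Cinv, expect)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        try:
            k_p = _kmult_stat(Ym[perm], Cinv, expect)
        except DegenerateStatisticError:
            continue
        if k_p >= k_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return KmultResult(
        k_mult=float(k_obs), p=float(p), n_perm=n_perm, seed=seed,
        n_tips=N, n_traits=Ym.shape[1],
    )


# ---------------------------------------------------------------------------
# clade evolutionary-rate comparison (sigma^2_mult)

@dataclass
class RateComparisonResult:
    sigma2: dict[str, float]
    sigma2_pooled: float
    ratio: float
    p: float
    n_iter: int
    seed: int | None
    null_method: str


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w[0] <= 0:
        w = w + (_RIDGE - min(0.0, w[0]))
        logger.warning("covariance not positive definite; eigenvalues ridged")
    return (V / np.sqrt(w)) @ V.T


def compare_evol_rates(
    Y: pd.DataFrame | np.ndarray,
    phylo: Phylogeny,
    group_of_tip: dict[str, str] | pd.Series,
    n_iter: int = 1000,
    seed: int | None = 0,
    null_method: str = "simulation",
    allow_single_group: bool = False,
) -> RateComparisonResult:
    """Net multivariate BM rate (sigma^2_mult) per group of tips.

    With U = C^{-1/2} (Y - 1a), a group's rate is sum of its tips' squared
    U-row norms / (N_g * p); the test statistic is the max/min rate ratio.
    The null distribution is built either by simulating BM at the pooled
    common rate on the tree (``simulation``, the default) or by permuting
    group labels across tips (``permutation``).
    """
    if null_method not in ("simulation", "permutation"):
        raise ValidationError(f"unknown null_method {null_method!r}")
    Ym = _align_traits(Y, phylo)
    N, p = Ym.shape
    groups = pd.Series(dict(group_of_tip)) if isinstance(group_of_tip, dict) else group_of_tip
    missing = [l for l in phylo.tip_labels if l not in groups.index]
    if missing:
        raise ValidationError(f"tips without a group: {missing}")
    glabels = groups.loc[phylo.tip_labels].to_numpy()
    names, counts = np.unique(glabels, return_counts=True)
    if len(names) < 2 and not allow_single_group:
        raise ValidationError("rate comparison needs at least two groups of tips")
    small = [str(g) for g, c in zip(names, counts) if c < 3]
    if small:
        raise ValidationError(f"groups with fewer than 3 tips: {small}")

    C = phylo.covariance()
    Cinv_sqrt = _inv_sqrt(C)
    cho = _safe_cho_factor(C)
    ones = np.ones(N)
    w = sla.cho_solve(cho, ones)

    def rates_from(Ymat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = w @ Ymat / (ones @ w)
        U = Cinv_sqrt @ (Ymat - a)
        return (U * U).sum(axis=1), a

    norms, _ = rates_from(Ym)
    total = float(norms.sum())
    if total <= 0:
        raise DegenerateStatisticError("identical trait rows: rates undefined")
    masks = [glabels == g for g in names]
    sig = np.array([norms[m].sum() / (m.sum() * p) for m in masks])
    sigma2_pooled = total / (N * p)
    ratio_obs = float(sig.max() / sig.min())

    rng = np.random.default_rng(seed)
    count = 0
    if null_method == "simulation":
        L = np.linalg.cholesky(C + _RIDGE * np.eye(N))
        scale = np.sqrt(sigma2_pooled)
        for _ in range(n_iter):
            Yn = scale * (L @ rng.standard_normal((N, p)))
            nn, _ = rates_from(Yn)
            s = np.array([nn[m].sum() / (m.sum() * p) for m in masks])
            if s.max() / s.min() >= ratio_obs:
                count += 1
    else:
        for _ in range(n_iter):
            perm = rng.permutation(N)
            nn = norms[perm]
            s = np.array([nn[m].sum() / (m.sum() * p) for m in masks])
            if s.max() / s.min() >= ratio_obs:
                count += 1
    pval = (count + 1) / (n_iter + 1)
    return RateComparisonResult(
        sigma2={str(g): float(s) for g, s in zip(names, sig)},
        sigma2_pooled=float(sigma2_pooled), ratio=ratio_obs, p=float(pval),
        n_iter=n_iter, seed=seed, null_method=null_method,
    )


# ---------------------------------------------------------------------------
# ML Brownian-motion models on ordination axes

@dataclass
class BMFit:
    sigma2: np.ndarray  # per axis
    mean: np.ndarray  # per axis
    loglik: float
    aicc: float
    n_params: int
    n_tips: int
    n_axes: int


def _bm_profile(Ym: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-axis ML mean, rate and total log-likelihood for fixed C."""
    N, q = Ym.shape
    cho = _safe_cho_factor(C)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ones = np.ones(N)
    w = sla.cho_solve(cho, ones)
    denom = ones @ w
    a = w @ Ym / denom
    E = Ym - a
    CE = sla.cho_solve(cho, E)
    s2 = np.einsum("ij,ij->j", E, CE) / N
    if np.any(s2 <= 0):
        raise DegenerateStatisticError("zero ML rate: constant axis values")
    ll = float(-0.5 * np.sum(N * np.log(2 * np.pi * s2) + logdet + N))
    return a, s2, ll


def _aicc(loglik: float, k: int, n_eff: int) -> float:
    if n_eff <= k + 1:
        raise DegenerateStatisticError(
            f"AICc undefined: effective sample size {n_eff} <= parameters {k} + 1"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def fit_bm(Y: pd.DataFrame | np.ndarray, phylo: Phylogeny) -> BMFit:
    """Single-rate Brownian motion fitted by ML, axis by axis.

    Axes are treated as independent Gaussian traits: per axis, the GLS root
    mean and sigma^2 = E'C^-1 E / N; logLik sums across axes; AICc uses
    k = 2 * n_axes parameters and effective sample size N * n_axes.
    """
    Ym = _align_traits(Y, phylo)
    C = phylo.covariance()
    a, s2, ll = _bm_profile(Ym, C)
    N, q = Ym.shape
    k = 2 * q
    return BMFit(
        sigma2=s2, mean=a, loglik=ll, aicc=_aicc(ll, k, N * q),
        n_params=k, n_tips=N, n_axes=q,
    )


@dataclass
class ShiftFit:
    node_id: str
    clade_tips: list[str]
    rate_multiplier: float
    loglik: float
    aicc: float
    loglik_single: float
    aicc_single: float
    delta_aicc: float  # aicc(shift) - aicc(single); negative favours the shift
    lr: float  # 2 * (loglik - loglik_single)
    n_params: int


def fit_clade_shift(
    Y: pd.DataFrame | np.ndarray,
    phylo: Phylogeny,
    node_id: str,
    min_clade_size: int = 3,
    log_r_bounds: tuple[float, float] = (np.log(1e-3), np.log(1e3)),
    tol: float = 1e-6,
    fixed_r: float | None = None,
) -> ShiftFit:
    """ML fit of a BM model with one clade-wide rate multiplier.

    Edges of the clade subtended by ``node_id`` (stem included) evolve at
    r times the background rate; per-axis means and rates are profiled out
    and r is found by bounded 1-D optimisation of the log-likelihood on
    log r. The single-rate model is the nested r = 1 case, so the shift
    log-likelihood is never lower.
    """
    Ym = _align_traits(Y, phylo)
    node = phylo.node(node_id)
    if node.parent_node is None:
        raise ValidationError(
            "a shift at the root is indistinguishable from the global rate"
        )
    tips = phylo.clade_tips(node_id)
    if len(tips) < min_clade_size:
        raise ValidationError(
            f"clade at {node_id} has {len(tips)} tips < min_clade_size {min_clade_size}"
        )
    C = phylo.covariance()
    M = phylo.shift_component(node_id)
    N, q = Ym.shape

    def negll(log_r: float) -> float:
        r = np.exp(log_r)
        try:
            return -_bm_profile(Ym, C + (r - 1.0) * M)[2]
        except (DegenerateStatisticError, np.linalg.LinAlgError):
            return np.inf

    ll_single = _bm_profile(Ym, C)[2]
    if fixed_r is not None:
        r_hat, ll = float(fixed_r), float(-negll(np.log(fixed_r)))
    else:
        res = minimize_scalar(
            negll, bounds=log_r_bounds, method="bounded",
            options={"xatol": tol},
        )
        # nesting guard: never report worse than r = 1
        if -res.fun < ll_single:
            r_hat, ll = 1.0, ll_single
        else:
            r_hat, ll = float(np.exp(res.x)), float(-res.fun)
    k_single = 2 * q
    k_shift = 2 * q + 1
    aicc_single = _aicc(ll_single, k_single, N * q)
    aicc_shift = _aicc(ll, k_shift, N * q)
    return ShiftFit(
        node_id=node_id, clade_tips=tips, rate_multiplier=r_hat,
        loglik=ll, aicc=aicc_shift, loglik_single=float(ll_single),
        aicc_single=aicc_single, delta_aicc=aicc_shift - aicc_single,
        lr=2.0 * (ll - ll_single), n_params=k_shift,
    )


@dataclass
class ShiftSearchResult:
    best: ShiftFit | None
    single: BMFit
    shift_supported: bool
    lr_cutoff: float
    node_table: pd.DataFrame
    n_null: int
    seed: int | None


def _eligible_nodes(phylo: Phylogeny, min_clade_size: int) -> list[str]:
    out = []
    for node_id in phylo.internal_node_ids:
        if node_id == phylo.root_id:
            continue
        if len(phylo.clade_tips(node_id)) >= min_clade_size:
            out.append(node_id)
    return out


def _best_shift(
    Ym: np.ndarray, phylo: Phylogeny, node_ids: list[str], min_clade_size: int
) -> tuple[ShiftFit, list[ShiftFit]]:
    fits = [
        fit_clade_shift(Ym, phylo, nid, min_clade_size=min_clade_size)
        for nid in node_ids
    ]
    best = max(fits, key=lambda f: f.loglik)
    return best, fits


def search_rate_shifts(
    Y: pd.DataFrame | np.ndarray,
    phylo: Phylogeny,
    max_shifts: int = 1,
    min_clade_size: int = 3,
    n_null: int = 100,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ShiftSearchResult:
    """Exhaustive single-shift search with a simulation-based cutoff.

    Every eligible internal node (non-root, clade of at least
    ``min_clade_size`` tips) is fitted as a candidate shift and ranked by
    log-likelihood. The decision threshold is the (1 - alpha) quantile of
    the best-node likelihood-ratio statistic over ``n_null`` datasets
    simulated under the fitted single-rate BM, so the null false-positive
    rate is alpha by construction. ``max_shifts = 0`` returns the
    single-rate fit only.
    """
    Ym = _align_traits(Y, phylo)
    single = fit_bm(Ym, phylo)
    if max_shifts == 0:
        return ShiftSearchResult(
            best=None, single=single, shift_supported=False, lr_cutoff=np.inf,
            node_table=pd.DataFrame(), n_null=0, seed=seed,
        )
    node_ids = _eligible_nodes(phylo, min_clade_size)
    if not node_ids:
        raise ValidationError("no eligible internal node for a shift")
    best, fits = _best_shift(Ym, phylo, node_ids, min_clade_size)

    rng = np.random.default_rng(seed)
    C = phylo.covariance()
    L = np.linalg.cholesky(C + _RIDGE * np.eye(len(C)))
    scales = np.sqrt(single.sigma2)
    null_lr = np.empty(n_null)
    for b in range(n_null):
        Yn = (L @ rng.standard_normal(Ym.shape)) * scales
        nb, _ = _best_shift(Yn, phylo, node_ids, min_clade_size)
        null_lr[b] = nb.lr
    cutoff = float(np.quantile(null_lr, 1.0 - alpha))
    table = pd.DataFrame(
        {
            "node_id": [f.node_id for f in fits],
            "clade_size": [len(f.clade_tips) for f in fits],
            "rate_multiplier": [f.rate_multiplier for f in fits],
            "loglik": [f.loglik for f in fits],
            "lr": [f.lr for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.delta_aicc for f in fits],
        }
    ).sort_values("loglik", ascending=False, ignore_index=True)
    return ShiftSearchResult(
        best=best, single=single, shift_supported=bool(best.lr > cutoff),
        lr_cutoff=cutoff, node_table=table, n_null=n_null, seed=seed,
    )


# ---------------------------------------------------------------------------
# species -> tip resolution

@dataclass
class TipResolution:
    species_to_tip: dict[str, str]
    samples: pd.DataFrame  # metadata rows retained for species-level analyses
    excluded_species: dict[str, str] = field(default_factory=dict)


def resolve_tips(
    meta: pd.DataFrame,
    phylo: Phylogeny,
    subspecies_choice: dict[str, str] | None = None,
) -> TipResolution:
    """Map each analysis species to exactly one tree tip.

    A species matches its own name directly; where several subspecies were
    sampled and the tree carries subspecies-level tips, the configured
    choice (e.g. which of two named subspecies represents the species)
    decides which tip and which samples are used. Unmatched species are
    excluded and reported.
    """
    subspecies_choice = subspecies_choice or {}
    tips = set(phylo.tip_labels)
    mapping: dict[str, str] = {}
    excluded: dict[str, str] = {}
    keep_rows: list[str] = []
    for sp, grp in meta.groupby("species"):
        ssps = sorted({s for s in grp["subspecies"] if s})
        if sp in tips:
            mapping[sp] = sp
            keep_rows.extend(grp["sample_id"])
            continue
        chosen = subspecies_choice.get(sp)
        if chosen and f"{sp} {chosen}" in tips:
            mapping[sp] = f"{sp} {chosen}"
            keep_rows.extend(grp.loc[grp["subspecies"] == chosen, "sample_id"])
            continue
        cand = [s for s in ssps if f"{sp} {s}" in tips]
        if len(cand) == 1:
            mapping[sp] = f"{sp} {cand[0]}"
            keep_rows.extend(grp.loc[grp["subspecies"] == cand[0], "sample_id"])
            continue
        reason = (
            "multiple subspecies tips and no configured choice"
            if len(cand) > 1
            else "no matching tip in tree"
        )
        excluded[sp] = reason
        logger.warning("species %s excluded from tree matching: %s", sp, reason)
    return TipResolution(
        species_to_tip=mapping,
        samples=meta.loc[meta["sample_id"].isin(keep_rows)].copy(),
        excluded_species=excluded,
    )
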