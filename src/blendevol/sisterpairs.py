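"""Sister-species-pair dissimilarity and its predictors.

For each pair of sister species the mean blend distance between their
samples is regressed (Gaussian GLM with identity link, i.e. OLS) on range
overlap, with divergence time (branch length, Myr) as a covariate: recently
diverged pairs are expected to differ less regardless of sympatry, so the
branch-length term controls for phylogenetic effects when asking whether
overlapping ranges drive blend divergence.

Pairs file dialect: CSV ``species_a,species_b,range_overlap,branch_length_myr``
(overlap is a proportion in [0, 1], taken from the literature rather than
computed here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_peaktables import ValidationError
from .multivariate import DistanceMatrix

logger = logging.getLogger("blendevol")

PAIR_COLUMNS = ["species_a", "species_b", "range_overlap", "branch_length_myr"]


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pairs file missing columns: {missing}")
    df = df[PAIR_COLUMNS].copy()
    if ((df["range_overlap"] < 0) | (df["range_overlap"] > 1)).any():
        raise ValidationError("range_overlap must lie in [0, 1]")
    if (df["branch_length_myr"] <= 0).any():
        raise ValidationError("branch_length_myr must be positive")
    return df


def pair_dissimilarity(
    D: DistanceMatrix,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
    method: str = "samples",
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean between-species blend distance for each sister pair.

    ``samples`` (default) averages ``D`` over every cross-species sample
    pair; ``centroids`` takes the Euclidean distance between the species'
    mean positions in the transformed blend space (``traits``: sample x
    compound matrix on the same transform as ``D``). Pairs with a missing
    species are dropped and logged.
    """
    if method not in ("samples", "centroids"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "centroids" and traits is None:
        raise ValidationError("centroid mode needs the sample trait matrix")
    species = meta.loc[D.labels, "species"]
    pos = {l: i for i, l in enumerate(D.labels)}
    rows = []
    for rec in pairs.itertuples(index=False):
        ids_a = [l for l, sp in species.items() if sp == rec.species_a]
        ids_b = [l for l, sp in species.items() if sp == rec.species_b]
        if not ids_a or not ids_b:
            logger.warning(
                "pair %s-%s dropped: species without samples",
                rec.species_a, rec.species_b,
            )
            continue
        if method == "samples":
            block = D.values[np.ix_([pos[l] for l in ids_a], [pos[l] for l in ids_b])]
            value = float(block.mean())
        else:
            ca = traits.loc[ids_a].mean(axis=0).to_numpy()
            cb = traits.loc[ids_b].mean(axis=0).to_numpy()
            value = float(np.linalg.norm(ca - cb))
        rows.append(
            {
                "species_a": rec.species_a,
                "species_b": rec.species_b,
                "range_overlap": rec.range_overlap,
                "branch_length_myr": rec.branch_length_myr,
                "mean_dissimilarity": value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    r2: float
    n: int


def gaussian_glm(
    data: pd.DataFrame, response: str, predictors: list[str]
) -> RegressionResult:
    """Gaussian GLM with identity link (ordinary least squares) and t-tests.

    An intercept is always included. Rank-deficient designs raise a
    collinearity error naming the offending columns.
    """
    y = data[response].to_numpy(dtype=float)
    X = data[list(predictors)].astype(float)
    X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValidationError(
            f"need more observations ({len(y)}) than coefficients ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(corr) > 1 else tuple(X.columns[1:])
        raise ValidationError(
            f"design matrix is rank deficient (collinear columns, e.g. {worst})"
        )
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues, pvalues=fit.pvalues,
        df_resid=int(fit.df_resid), r2=float(fit.rsquared), n=len(y),
    )
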