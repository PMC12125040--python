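"""Cross-sample peak alignment and blend-matrix assembly.

Two peaks from different chromatograms are treated as the same compound
when their two most intense fragment ions correspond exactly and their
retention indices agree to within a relative tolerance (0.8% by default,
calibrated in the source study against the RI spread of cholesterol across
batches). Clustering is deterministic: peaks are visited in RI order and
greedily attached to the nearest existing cluster whose running consensus
they match, with at most one peak per sample per cluster.

The aligned sample x compound matrix of relative amounts (0 = not
detected) carries each compound's consensus RI and is partitioned into
early-eluting (RI <= 1600, the volatile candidate signals) and
mid/late-eluting (RI > 1600, the fatty-acid-ester "matrix") fractions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_peaktables import ValidationError

logger = logging.getLogger("blendevol")

DEFAULT_RI_TOLERANCE = 0.008
DEFAULT_VOLATILITY_CUTOFF = 1600.0


def peaks_match(
    ri_p: float,
    ions_p: tuple[int, int],
    ri_q: float,
    ions_q: tuple[int, int],
    rel_tol: float = DEFAULT_RI_TOLERANCE,
    ordered_ions: bool = False,
) -> bool:
    """Alignment predicate for two annotated peaks.

    True iff the top-2 ion pairs correspond exactly (unordered by default;
    ``ordered_ions=True`` additionally requires the same intensity ranking)
    and |RI_p - RI_q| <= rel_tol * mean(RI_p, RI_q). The mean-of-the-two
    base makes the predicate symmetric. The boundary is inclusive.
    """
    if ordered_ions:
        if tuple(ions_p) != tuple(ions_q):
            return False
    elif frozenset(ions_p) != frozenset(ions_q):
        return False
    base = 0.5 * (ri_p + ri_q)
    return abs(ri_p - ri_q) <= rel_tol * base


@dataclass
class CompoundCluster:
    """A group of peaks aligned as one compound across samples."""

    compound_id: str
    consensus_ri: float
    top_ions: frozenset[int]
    ordered_ions: tuple[int, int] | None
    members: list[tuple[str, int]] = field(default_factory=list)  # (sample_id, peak row)
    member_ris: list[float] = field(default_factory=list)

    def sample_ids(self) -> set[str]:
        return {s for s, _ in self.members}


class _Cluster:
    """Mutable working cluster during greedy linkage."""

    __slots__ = ("ions", "ordered", "rows", "ri_sum")

    def __init__(self, ions: frozenset[int], ordered: tuple[int, int]):
        self.ions = ions
        self.ordered = ordered
        self.rows: dict[str, int] = {}  # sample_id -> position in peak arrays
        self.ri_sum = 0.0

    @property
    def consensus_ri(self) -> float:
        return self.ri_sum / len(self.rows)

    def add(self, sample_id: str, pos: int, ri: float) -> None:
        self.rows[sample_id] = pos
        self.ri_sum += ri

    def remove(self, sample_id: str, ri: float) -> None:
        del self.rows[sample_id]
        self.ri_sum -= ri


def cluster_peaks(
    annotated: pd.DataFrame,
    rel_tol: float = DEFAULT_RI_TOLERANCE,
    ordered_ions: bool = False,
) -> list[CompoundCluster]:
    """Greedy consensus-linkage clustering of annotated peaks into compounds.

    Peaks (internal-standard rows excluded) are sorted by RI and attached
    one at a time to the matching cluster whose consensus RI is closest;
    a peak that matches no cluster seeds a new one. If the chosen cluster
    already holds a peak from the same sample, the peak closer to the
    consensus stays (ties broken by higher intensity, then by input order),
    and the displaced peak is re-inserted through the same procedure, so
    every peak ends up in exactly one cluster. Matching against the running
    consensus bounds chain growth. The result is ordered by consensus RI
    and the whole procedure is invariant to input row order.
    """
    df = annotated
    if "retention_index" not in df.columns:
        raise ValidationError("peaks must carry a retention_index column")
    if "is_internal_standard" in df.columns:
        df = df[~df["is_internal_standard"]]

    # deterministic visiting order: RI, then sample, then intensity
    order = np.lexsort(
        (
            df["intensity"].to_numpy(),
            df["sample_id"].to_numpy(),
            df["retention_index"].to_numpy(),
        )
    )
    rows = df.index.to_numpy()[order]
    ris = df["retention_index"].to_numpy()[order]
    intens = df["intensity"].to_numpy()[order]
    samples = df["sample_id"].to_numpy()[order]
    mz1 = df["mz1"].to_numpy()[order]
    mz2 = df["mz2"].to_numpy()[order]
    ion_sets = [frozenset((int(a), int(b))) for a, b in zip(mz1, mz2)]
    ion_pairs = list(zip(mz1.tolist(), mz2.tolist()))

    clusters: list[_Cluster] = []
    # insertion worklist: displaced peaks re-enter here (LIFO; bounded because
    # a displaced peak is always farther from every consensus it lost)
    stack: list[int] = []

    def try_place(pos: int) -> None:
        ri = ris[pos]
        key = ion_pairs[pos] if ordered_ions else ion_sets[pos]
        candidates = []
        for c in clusters:
            ckey = c.ordered if ordered_ions else c.ions
            if ckey != key:
                continue
            if peaks_match(
                ri, ion_pairs[pos], c.consensus_ri, c.ordered,
                rel_tol=rel_tol, ordered_ions=False,
            ):
                candidates.append((abs(ri - c.consensus_ri), c))
        candidates.sort(key=lambda t: t[0])
        for _, c in candidates:
            sid = samples[pos]
            incumbent = c.rows.get(sid)
            if incumbent is None:
                c.add(sid, pos, ri)
                return
            d_new = abs(ri - c.consensus_ri)
            d_old = abs(ris[incumbent] - c.consensus_ri)
            new_wins = d_new < d_old or (
                d_new == d_old and intens[pos] > intens[incumbent]
            )
            if new_wins:
                c.remove(sid, ris[incumbent])
                c.add(sid, pos, ri)
                stack.append(incumbent)
                return
            # incumbent stays; try next-nearest candidate cluster
        new = _Cluster(ion_sets[pos], ion_pairs[pos])
        new.add(samples[pos], pos, ri)
        clusters.append(new)

    budget = 10 * max(1, len(rows))  # displacement chains are short in practice
    for pos in range(len(rows)):
        try_place(pos)
        while stack:
            budget -= 1
            if budget < 0:
                raise RuntimeError("clustering displacement chain did not terminate")
            try_place(stack.pop())

    clusters.sort(key=lambda c: c.consensus_ri)
    out: list[CompoundCluster] = []
    width = max(4, len(str(len(clusters))))
    for k, c in enumerate(clusters):
        positions = sorted(c.rows.values())
        out.append(
            CompoundCluster(
                compound_id=f"c{k + 1:0{width}d}",
                consensus_ri=c.consensus_ri,
                top_ions=c.ions,
                ordered_ions=c.ordered,
                members=[(samples[p], int(rows[p])) for p in positions],
                member_ris=[float(ris[p]) for p in positions],
            )
        )
    logger.info("clustered %d peaks into %d compounds", len(rows), len(out))
    return out


@dataclass
class BlendMatrix:
    """Aligned sample x compound matrix of relative amounts.

    ``data`` has one row per valid sample and one column per compound
    (0 = not detected); ``compounds`` carries per-column consensus RI, the
    top-ion pair and the volatility partition label.
    """

    data: pd.DataFrame
    compounds: pd.DataFrame  # index compound_id; consensus_ri, mz1, mz2, partition
    cutoff: float = DEFAULT_VOLATILITY_CUTOFF

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_columns(self, compound_ids) -> "BlendMatrix":
        ids = list(compound_ids)
        return BlendMatrix(
            data=self.data[ids].copy(),
            compounds=self.compounds.loc[ids].copy(),
            cutoff=self.cutoff,
        )

    def to_tsv(self, path) -> None:
        header = self.data.copy()
        header.columns = [
            f"{cid}|RI={self.compounds.loc[cid, 'consensus_ri']:.1f}"
            for cid in header.columns
        ]
        header.to_csv(path, sep="\t", index_label="sample_id")

    def clusters_to_json(self, path, clusters: list[CompoundCluster]) -> None:
        payload = [
            {
                "compound_id": c.compound_id,
                "consensus_ri": c.consensus_ri,
                "top_ions": sorted(c.top_ions),
                "n_members": len(c.members),
                "samples": sorted(c.sample_ids()),
            }
            for c in clusters
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_matrix_tsv(path, cutoff: float = DEFAULT_VOLATILITY_CUTOFF) -> BlendMatrix:
    """Read a blend matrix written by :meth:`BlendMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    ids, ris = [], []
    for col in df.columns:
        try:
            cid, ri_part = col.split("|RI=")
        except ValueError as exc:
            raise ValidationError(f"malformed matrix column {col!r}") from exc
        ids.append(cid)
        ris.append(float(ri_part))
    df.columns = ids
    df.index = df.index.astype(str)
    comp = pd.DataFrame(
        {"consensus_ri": ris, "mz1": pd.NA, "mz2": pd.NA},
        index=pd.Index(ids, name="compound_id"),
    )
    comp["partition"] = np.where(comp["consensus_ri"] <= cutoff, "early", "mid_late")
    return BlendMatrix(data=df, compounds=comp, cutoff=cutoff)


def build_matrix(
    clusters: list[CompoundCluster],
    annotated: pd.DataFrame,
    sample_ids=None,
    cutoff: float = DEFAULT_VOLATILITY_CUTOFF,
) -> BlendMatrix:
    """Assemble the blend matrix from clusters; absent compound = 0."""
    if sample_ids is None:
        sample_ids = sorted(annotated["sample_id"].unique())
    sample_ids = list(sample_ids)
    ids = [c.compound_id for c in clusters]
    mat = pd.DataFrame(0.0, index=pd.Index(sample_ids, name="sample_id"), columns=ids)
    rel = annotated["relative_amount"]
    for c in clusters:
        for sid, row in c.members:
            mat.loc[sid, c.compound_id] = rel.loc[row]
    comp = pd.DataFrame(
        {
            "consensus_ri": [c.consensus_ri for c in clusters],
            "mz1": [c.ordered_ions[0] for c in clusters],
            "mz2": [c.ordered_ions[1] for c in clusters],
        },
        index=pd.Index(ids, name="compound_id"),
    )
    comp["partition"] = np.where(comp["consensus_ri"] <= cutoff, "early", "mid_late")
    return BlendMatrix(data=mat, compounds=comp, cutoff=cutoff)


def split_by_volatility(
    matrix: BlendMatrix, cutoff: float | None = None
) -> tuple[BlendMatrix, BlendMatrix]:
    """Partition columns into early (RI <= cutoff) and mid/late (RI > cutoff).

    The boundary is inclusive on the early side: a compound at exactly the
    cutoff RI counts as early-eluting.
    """
    if cutoff is None:
        cutoff = matrix.cutoff
    early_ids = matrix.compounds.index[matrix.compounds["consensus_ri"] <= cutoff]
    late_ids = matrix.compounds.index[matrix.compounds["consensus_ri"] > cutoff]
    return matrix.subset_columns(early_ids), matrix.subset_columns(late_ids)


def blend_percentages(
    matrix: BlendMatrix,
    meta: pd.DataFrame,
    scope: str = "total",
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Per-species mean share of each compound within a blend scope.

    Within each sample, a compound's share is its relative amount divided by
    the summed amount over the scope's columns (``total`` = all compounds,
    ``early`` = early-eluting only); shares therefore sum to 1 within a
    sample that has a nonzero scope total. Samples with a zero scope total
    contribute nothing to the species mean (logged). Columns of the result
    span the scope's compounds; rows are species.
    """
    if scope not in ("total", "early"):
        raise ValidationError(f"unknown scope {scope!r}")
    sub = matrix
    if scope == "early":
        sub, _ = split_by_volatility(matrix, cutoff)
    values = sub.data
    totals = values.sum(axis=1)
    zero = totals[totals == 0].index
    for sid in zero:
        logger.warning("sample %s has zero %s-blend total; excluded from shares", sid, scope)
    shares = values.loc[totals > 0].div(totals[totals > 0], axis=0)
    species = meta.loc[shares.index, "species"]
    return shares.groupby(species.to_numpy()).mean().rename_axis("species")
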