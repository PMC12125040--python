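"""Synthetic GC-MS datasets with full ground truth.

Generates everything the pipeline consumes -- per-sample peak tables,
per-batch alkane ladders, sample metadata and a dated phylogeny -- from a
known generative model, so that alignment and the comparative statistics
can be checked against truth:

* a pure-birth tree (or a user-supplied newick) with a configured
  root-to-tip depth in Myr;
* species mean log relative amounts evolving by Brownian motion along the
  tree (optionally with clade-wide rate multipliers, the planted "shifts");
* individuals as species mean + independent Gaussian intraspecific noise
  on the log scale, exponentiated to positive relative amounts with a
  detection threshold (absent compound = no peak);
* each compound carries a true retention index and a unique top-ion pair;
  "decoy" compounds reuse another compound's ion pair at a large RI offset
  and are the designed adversarial case for the top-2-ion alignment rule;
* observed RIs add per-batch drift and per-peak jitter; each batch's
  alkane ladder is linear in carbon number so the RI computation inverts
  the construction exactly when jitter is zero;
* an internal-standard peak (ions 43/61, RI ~1585) is spiked into every
  sample, with a lognormal per-sample intensity so that relative amounts,
  not raw intensities, are the invariant quantity.

The defaults emulate the structure of the study the pipeline is built
for -- tens of species, a few conspecific males each, a handful of
instrument batches, prominent early-eluting volatiles over a heavier
ester matrix -- at a size where ground-truth recovery is exact for the
"clean" regime (RI jitter well inside the alignment tolerance, decoys
well outside it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CompoundCluster
from .io_peaktables import SUBCLADES, ValidationError
from .phylocomp import Phylogeny

logger = logging.getLogger("blendevol")

# plausible EI fragment ions for ester/terpenoid chemistry; the internal
# standard's pair (43, 61) is reserved
_ION_POOL = [
    41, 43, 55, 57, 67, 69, 71, 79, 81, 83, 91, 93, 95, 105, 107, 117,
    119, 121, 131, 133, 145, 147, 161, 175, 189, 204, 218, 222,
]
_IS_IONS = (43, 61)
_IS_RI = 1585.0


@dataclass
class SimulationConfig:
    """Knobs of the generative model (defaults = the emulated study regime)."""

    n_tips: int = 30
    newick: str | None = None  # overrides n_tips when given
    tree_depth: float = 10.5  # root-to-tip, Myr
    n_compounds: int = 25
    early_fraction: float = 0.3  # fraction of compounds with RI <= 1600
    base_rate: float = 0.2  # BM rate, (log relative amount)^2 per Myr
    clade_multipliers: dict[str, float] = field(default_factory=dict)
    intraspecific_sd: float = 0.55  # log-scale, per compound
    n_individuals_per_species: int = 3
    n_batches: int = 3
    ri_jitter_sd: float = 1.0  # RI units, per peak
    batch_drift_sd: float = 0.5  # RI units, per batch
    decoy_fraction: float = 0.1
    decoy_min_offset: float = 0.06  # relative RI offset of a decoy from its twin
    detection_threshold: float = 0.01  # relative amount below which no peak is emitted
    is_intensity: float = 1e4  # nominal internal-standard area
    is_intensity_cv: float = 0.1  # lognormal sd of the per-sample IS area
    seed: int = 0

    def validate(self, clean: bool = True) -> None:
        for name in (
            "tree_depth", "base_rate", "intraspecific_sd", "ri_jitter_sd",
            "batch_drift_sd", "is_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.n_tips < 4:
            raise ValidationError("need at least 4 tips")
        if clean and 3.0 * self.ri_jitter_sd >= 0.008 * 700.0:
            raise ValidationError(
                "clean fixture requires 3 * ri_jitter_sd < 0.8% of the minimum "
                "compound RI (700)"
            )
        if clean and self.decoy_min_offset <= 0.05:
            raise ValidationError(
                "clean fixture requires decoy RI offsets above 5%"
            )


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(
    n_tips: int, seed: int | np.random.Generator, depth: float = 10.5
) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips scaled to ``depth`` Myr.

    Exponential waiting times between speciation events; the tree is
    ultrametric and its root-to-tip depth is rescaled to ``depth`` exactly.
    Tips are labelled ``sp01`` ... in order of appearance.
    """
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    class _N:
        __slots__ = ("children", "start", "length", "label")

        def __init__(self, start):
            self.children = []
            self.start = start
            self.length = 0.0
            self.label = None

    t = 0.0
    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = active[:]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.length = t - node.start
        kids = [_N(t), _N(t)]
        node.children = kids
        active[k:k + 1] = kids
    t += rng.exponential(1.0 / len(active))
    for k, node in enumerate(active):
        node.length = t - node.start
        node.label = f"sp{k + 1:02d}"
    scale = depth / t

    def to_newick(node) -> str:
        if not node.children:
            return f"{node.label}:{node.length * scale:.10f}"
        inner = ",".join(to_newick(ch) for ch in node.children)
        return f"({inner}):{node.length * scale:.10f}"

    newick = f"({','.join(to_newick(ch) for ch in root.children)});"
    return Phylogeny.from_newick(newick, is_path=False)


def default_pupal_node(phylo: Phylogeny, target_fraction: float = 0.5) -> str:
    """Pick the "pupal-mating" clade for the synthetic metadata.

    The larger child of the root plays the role of the genus with both
    mating strategies; within it, the internal node whose clade is closest
    to the target share of that genus's tips is designated pupal-mating,
    constrained so both strategies keep at least 3 species. The same node
    is the default planted-shift clade.
    """
    children = phylo.tree.seed_node.child_nodes()
    sizes = [len(list(ch.leaf_iter())) for ch in children]
    genus_node = children[int(np.argmax(sizes))]
    genus_size = max(sizes)
    genus_internal = {
        id(n) for n in genus_node.preorder_iter() if not n.is_leaf()
    } - {id(genus_node)}
    target = target_fraction * genus_size
    best, best_err = None, np.inf
    for nid in phylo.internal_node_ids:
        if id(phylo.node(nid)) not in genus_internal:
            continue
        size = len(phylo.clade_tips(nid))
        if size < 3 or genus_size - size < 3:
            continue
        err = abs(size - target)
        if err < best_err:
            best, best_err = nid, err
    if best is None:
        raise ValidationError(
            "no internal clade leaves at least 3 species on each side; "
            "use a larger tree"
        )
    return best


# ---------------------------------------------------------------------------
# blend simulation

def _edge_rates(phylo: Phylogeny, clade_multipliers: dict[str, float]):
    rates = {id(n): 1.0 for n in phylo.tree.preorder_node_iter()}
    for node_id, r in clade_multipliers.items():
        if r <= 0:
            raise ValidationError("clade rate multipliers must be positive")
        shift_node = phylo.node(node_id)
        for n in shift_node.preorder_iter():
            rates[id(n)] *= r
    return rates


def simulate_blends(
    phylo: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator,
    root_means: np.ndarray,
) -> pd.DataFrame:
    """Species mean log relative amounts by BM along the tree.

    Each branch adds independent N(0, base_rate * length * r) increments
    per compound, where r is the product of the clade multipliers covering
    the branch (stem edge of a shift clade included).
    """
    p = len(root_means)
    rates = _edge_rates(phylo, config.clade_multipliers)
    values: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    for node in phylo.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = np.asarray(root_means, dtype=float).copy()
        else:
            length = node.edge.length or 0.0
            var = config.base_rate * length * rates[id(node)]
            values[id(node)] = values[id(parent)] + rng.normal(
                0.0, np.sqrt(var), size=p
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return pd.DataFrame.from_dict(tips, orient="index").sort_index()


# ---------------------------------------------------------------------------
# rendering to the pipeline's input dialects

@dataclass
class SimulatedDataset:
    """A complete synthetic study plus its ground truth."""

    peaks: pd.DataFrame
    ladders: pd.DataFrame
    meta: pd.DataFrame
    newick: str
    phylo: Phylogeny
    compounds: pd.DataFrame  # truth: compound, true_ri, mz1, mz2, is_decoy, early
    species_log_means: pd.DataFrame  # species x compound (log scale)
    individuals: pd.DataFrame  # sample x compound relative amounts (0 = absent)
    peak_truth: list[str]  # per peak row: true compound id or "__IS__"
    pupal_node_id: str | None
    config: SimulationConfig

    def truth_partition(self) -> dict[str, set[int]]:
        """Ground-truth compound partition over peak rows (IS rows excluded)."""
        part: dict[str, set[int]] = {}
        for row, label in enumerate(self.peak_truth):
            if label == "__IS__":
                continue
            part.setdefault(label, set()).add(row)
        return part


def _ladder_rt(batch_index: int, ri: np.ndarray | float):
    a = 0.5 + 0.05 * batch_index
    slope = 1.0 + 0.02 * batch_index
    return a + slope * (np.asarray(ri, dtype=float) / 100.0)


def _compound_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = config.n_compounds
    n_early = max(1, round(config.early_fraction * p))
    n_decoy = round(config.decoy_fraction * p)
    ris = np.concatenate(
        [
            rng.uniform(700.0, 1600.0, size=n_early),
            rng.uniform(1650.0, 2950.0, size=p - n_early),
        ]
    )
    pairs = [
        (a, b)
        for i, a in enumerate(_ION_POOL)
        for b in _ION_POOL[i + 1:]
        if {a, b} != set(_IS_IONS)
    ]
    chosen = rng.choice(len(pairs), size=p, replace=False)
    mz = [pairs[int(i)] for i in chosen]
    rows = []
    for k in range(p):
        mz1, mz2 = (mz[k][1], mz[k][0]) if rng.random() < 0.5 else mz[k]
        rows.append(
            {
                "compound": f"t{k + 1:03d}",
                "true_ri": float(ris[k]),
                "mz1": mz1,
                "mz2": mz2,
                "is_decoy": False,
                "early": bool(ris[k] <= 1600.0),
            }
        )
    # decoys reuse an existing ion pair at a relative RI offset > decoy_min_offset
    twins = rng.choice(p, size=n_decoy, replace=False) if n_decoy else []
    for j, twin in enumerate(twins):
        base = rows[int(twin)]
        off = rng.uniform(config.decoy_min_offset, 2 * config.decoy_min_offset)
        ri_up = base["true_ri"] * (1 + off)
        ri_dn = base["true_ri"] * (1 - off)
        ri = ri_up if ri_up <= 2990.0 else ri_dn
        if ri < 700.0 or abs(ri - base["true_ri"]) / (
            0.5 * (ri + base["true_ri"])
        ) <= 0.05:
            raise ValidationError("decoy RI offset fell inside the tolerance")
        rows.append(
            {
                "compound": f"d{j + 1:03d}",
                "true_ri": float(ri),
                "mz1": base["mz1"],
                "mz2": base["mz2"],
                "is_decoy": True,
                "early": bool(ri <= 1600.0),
            }
        )
    return pd.DataFrame(rows).set_index("compound", drop=False)


def _assign_metadata(phylo: Phylogeny, pupal_node_id: str | None) -> pd.DataFrame:
    """Species-level taxonomy labels consistent with the simulated tree."""
    leaf_order = [lf.taxon.label for lf in phylo.tree.leaf_node_iter()]
    children = phylo.tree.seed_node.child_nodes()
    sizes = [len(list(ch.leaf_iter())) for ch in children]
    big = children[int(np.argmax(sizes))]
    heliconius = {lf.taxon.label for lf in big.leaf_iter()}
    non_h = [l for l in leaf_order if l not in heliconius]
    eueides = set(non_h[: (len(non_h) + 1) // 2])
    pupal = (
        set(phylo.clade_tips(pupal_node_id)) & heliconius if pupal_node_id else set()
    )

    h_order = [l for l in leaf_order if l in heliconius]
    h_subclades = [s for s in SUBCLADES if s not in ("basal", "Eueides")]
    blocks = np.array_split(np.arange(len(h_order)), len(h_subclades))
    sub_of = {}
    for sub, block in zip(h_subclades, blocks):
        for i in block:
            sub_of[h_order[i]] = sub
    rows = []
    for sp in sorted(leaf_order):
        if sp in heliconius:
            genus, sub = "Heliconius", sub_of[sp]
            strategy = "pupal" if sp in pupal else "free"
        elif sp in eueides:
            genus, sub, strategy = "Eueides", "Eueides", "free"
        else:
            genus, sub, strategy = "basal", "basal", "free"
        rows.append(
            {"species": sp, "genus_group": genus, "subclade": sub,
             "mating_strategy": strategy}
        )
    return pd.DataFrame(rows).set_index("species", drop=False)


def simulate_dataset(
    config: SimulationConfig, clean: bool = True
) -> SimulatedDataset:
    """Run the whole generative model and render the pipeline's inputs."""
    config.validate(clean=clean)
    rng = np.random.default_rng(config.seed)

    if config.newick:
        phylo = Phylogeny.from_newick(config.newick, is_path=False)
    else:
        phylo = simulate_tree(config.n_tips, rng, depth=config.tree_depth)
    try:
        pupal_node = default_pupal_node(phylo)
    except ValidationError:
        # tree too small to give both strategies >= 3 species; all free-mating
        logger.info("tree too small for a pupal clade; all species free-mating")
        pupal_node = None

    compounds = _compound_table(config, rng)
    n_all = len(compounds)
    # prominent early volatiles over a quieter ester matrix (log scale)
    root_means = np.where(
        compounds["early"].to_numpy(),
        rng.normal(1.0, 0.5, size=n_all),
        rng.normal(0.0, 0.5, size=n_all),
    )
    root_means[compounds["is_decoy"].to_numpy()] -= 0.5

    log_means = simulate_blends(phylo, config, rng, root_means)
    log_means.columns = compounds.index

    taxonomy = _assign_metadata(phylo, pupal_node)
    drift = rng.normal(0.0, config.batch_drift_sd, size=config.n_batches)

    meta_rows, peak_rows, truth = [], [], []
    individuals = {}
    sample_counter = 0
    for sp in log_means.index:
        for j in range(config.n_individuals_per_species):
            sid = f"{sp}_i{j + 1}"
            b = sample_counter % config.n_batches
            batch_id = f"b{b + 1}"
            sample_counter += 1
            tax = taxonomy.loc[sp]
            meta_rows.append(
                {
                    "sample_id": sid, "species": sp, "subspecies": "",
                    "subclade": tax["subclade"], "genus_group": tax["genus_group"],
                    "mating_strategy": tax["mating_strategy"], "sex": "male",
                    "rearing": "wild", "batch_id": batch_id,
                }
            )
            logs = log_means.loc[sp].to_numpy() + rng.normal(
                0.0, config.intraspecific_sd, size=n_all
            )
            amounts = np.exp(logs)
            amounts[amounts < config.detection_threshold] = 0.0
            individuals[sid] = amounts
            is_area = config.is_intensity * np.exp(
                rng.normal(0.0, config.is_intensity_cv)
            )
            for k, cid in enumerate(compounds.index):
                if amounts[k] == 0.0:
                    continue
                ri_obs = (
                    compounds.loc[cid, "true_ri"]
                    + drift[b]
                    + rng.normal(0.0, config.ri_jitter_sd)
                )
                peak_rows.append(
                    {
                        "sample_id": sid, "batch_id": batch_id,
                        "rt_min": float(_ladder_rt(b, ri_obs)),
                        "intensity": float(amounts[k] * is_area),
                        "mz1": int(compounds.loc[cid, "mz1"]),
                        "mz2": int(compounds.loc[cid, "mz2"]),
                    }
                )
                truth.append(cid)
            ri_is = _IS_RI + drift[b] + rng.normal(0.0, config.ri_jitter_sd)
            peak_rows.append(
                {
                    "sample_id": sid, "batch_id": batch_id,
                    "rt_min": float(_ladder_rt(b, ri_is)),
                    "intensity": float(is_area),
                    "mz1": _IS_IONS[0], "mz2": _IS_IONS[1],
                }
            )
            truth.append("__IS__")

    ladder_rows = [
        {"batch_id": f"b{b + 1}", "carbon_number": n,
         "rt_min": float(_ladder_rt(b, 100.0 * n))}
        for b in range(config.n_batches)
        for n in range(6, 41)
    ]
    peaks = pd.DataFrame(peak_rows)
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    ind = pd.DataFrame.from_dict(individuals, orient="index", columns=compounds.index)
    return SimulatedDataset(
        peaks=peaks, ladders=pd.DataFrame(ladder_rows), meta=meta,
        newick=phylo.to_newick(), phylo=phylo, compounds=compounds,
        species_log_means=log_means, individuals=ind, peak_truth=truth,
        pupal_node_id=pupal_node, config=config,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write the dataset in the pipeline's CSV/newick dialects plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": outdir / "peaks.csv",
        "ladders": outdir / "ladders.csv",
        "meta": outdir / "metadata.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    ds.peaks.to_csv(paths["peaks"], index=False)
    ds.ladders.to_csv(paths["ladders"], index=False)
    ds.meta.to_csv(paths["meta"], index=False)
    paths["tree"].write_text(ds.newick + "\n")
    cfg = asdict(ds.config)
    truth = {
        "config": cfg,
        "pupal_node_id": ds.pupal_node_id,
        "compounds": ds.compounds.to_dict(orient="records"),
        "peak_truth": ds.peak_truth,
        "species_log_means": {
            sp: [float(v) for v in row]
            for sp, row in ds.species_log_means.iterrows()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return {k: str(v) for k, v in paths.items()}


def evaluate_recovery(
    clusters: list[CompoundCluster], ds: SimulatedDataset
) -> dict[str, float]:
    """Compare recovered clusters with the ground-truth compound partition.

    ``exact``: 1.0 when the two partitions of peak rows are identical.
    ``fraction_recovered``: share of truth compounds recovered as an
    identical cluster (the headline recovery rate for stress fixtures).
    """
    truth_groups = {frozenset(v) for v in ds.truth_partition().values()}
    found = {frozenset(r for _, r in c.members) for c in clusters}
    matched = len(truth_groups & found)
    return {
        "exact": float(truth_groups == found),
        "fraction_recovered": matched / len(truth_groups),
        "n_truth": float(len(truth_groups)),
        "n_found": float(len(found)),
    }
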