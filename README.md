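# blendevol

Tools for studying the macroevolution of insect chemical blends — built
around the antiaphrodisiac pheromones that male *Heliconius* butterflies
transfer to females at mating. The package takes deconvolved GC-MS peak
lists of abdominal-gland extracts all the way to comparative-phylogenetic
statistics that ask whether mating strategy (pupal-mating vs free-mating
clades) shapes how these blends diversify.

It is aimed at chemical ecologists and comparative biologists who have
per-sample peak tables (retention time, intensity, top fragment ions), a
per-batch C6–C40 alkane ladder, sample metadata, and a dated phylogeny.

## What it computes

**Front end (peak tables → blend matrix)**

- Linear retention indices: `RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n))`
  against each batch's alkane ladder; no extrapolation beyond the ladder.
- Relative amounts: intensity divided by the internal-standard
  (2-acetoxytetradecane) intensity of the same chromatogram.
- Cross-batch alignment: two peaks are one compound iff their two most
  intense *m/z* ions correspond exactly and their RIs agree to ±0.8 %
  (of the mean RI; both knobs configurable). Deterministic greedy
  consensus-linkage, one peak per sample per compound.
- The sample × compound matrix, partitioned into early-eluting (RI ≤ 1600,
  the volatile candidate signals) and mid/late-eluting compounds (RI > 1600,
  the fatty-acid-ester matrix), plus per-species blend percentages.

**Statistics (blend matrix → inference)**

- Euclidean blend distances (optionally log(x+1)), Kruskal non-metric MDS
  on 5 axes, PERMANOVA (10,000 permutations), within-species dissimilarity,
  dispersion from the species' geometric-median composition, Welch t-tests.
- Multivariate phylogenetic signal
  `K_mult = [tr(EᵀE)/tr(EᵀC⁻¹E)] · (N−1)/(tr C − N/(1ᵀC⁻¹1))`
  (≈ 1 under Brownian motion), with tip-shuffling permutation tests.
- Net multivariate Brownian rates σ²_mult per clade and their max/min
  ratio, with a simulated (or permutation) null — the pupal- vs
  free-mating rate comparison.
- ML Brownian-motion models on ordination axes with a single clade-wide
  rate multiplier, searched over all internal nodes, with a
  simulation-derived likelihood-ratio cutoff for declaring a shift.
- Sister-species-pair dissimilarity regressed on range overlap with
  divergence time as a covariate (Gaussian GLM / OLS).
- A fully seeded synthetic-data generator (blends evolving by BM on a
  simulated or supplied tree, intraspecific noise, batch RI drift, decoy
  ions, internal standard) with complete ground truth.

## Worked example

```python
import blendevol as bv
from blendevol.io_peaktables import AlkaneLadder, annotate_peaks
from blendevol.multivariate import (euclidean_distances, permanova,
                                    within_species_distance, welch_t)
from blendevol.phylocomp import kmult, trait_matrix_from_blend

# 1. simulate a study: 30 species x 3 males, 25 compounds, 3 instrument batches
ds = bv.simulate_dataset(bv.SimulationConfig(n_tips=30, n_compounds=25, seed=1))

# 2. calibrate, annotate and align the peak tables
ladders = {b: AlkaneLadder(b, dict(zip(g["carbon_number"], g["rt_min"])))
           for b, g in ds.ladders.groupby("batch_id")}
ann = annotate_peaks(ds.peaks, ladders)
clusters = bv.cluster_peaks(ann.peaks)
matrix = bv.build_matrix(clusters, ann.peaks)
print("recovered compounds:", len(clusters),
      "| exact match to truth:", bool(bv.evaluate_recovery(clusters, ds)["exact"]))

# 3. species effect on blend composition
D = euclidean_distances(matrix, transform="log_plus_one")
res = permanova(D, ds.meta.loc[D.labels, "species"], n_perm=10_000, seed=1)
print(f"PERMANOVA species: R2 = {res.r2:.3f}, pseudo-F = {res.pseudo_f:.1f}, p = {res.p:.4f}")

# 4. do free-mating species vary more within species than pupal-mating ones?
within = within_species_distance(D, ds.meta)
strategy = ds.meta.groupby("species")["mating_strategy"].first()
genus = ds.meta.groupby("species")["genus_group"].first()
free = within[[s for s in within.index
               if genus[s] == "Heliconius" and strategy[s] == "free"]]
pupal = within[[s for s in within.index if strategy[s] == "pupal"]]
w = welch_t(free, pupal)
print(f"Welch within-species contrast: t = {w.t:.2f}, df = {w.df:.1f}, p = {w.p:.2f}")

# 5. phylogenetic signal of the species-mean blends
traits = trait_matrix_from_blend(matrix, ds.meta)
km = kmult(traits.loc[ds.phylo.tip_labels], ds.phylo, n_perm=1000, seed=1)
print(f"K_mult = {km.k_mult:.3f}, p = {km.p:.4f}")
```

Output:

```
recovered compounds: 27 | exact match to truth: True
PERMANOVA species: R2 = 0.885, pseudo-F = 16.0, p = 0.0001
Welch within-species contrast: t = -2.29, df = 8.6, p = 0.05
K_mult = 0.532, p = 0.0010
```

The 27 recovered compounds are the 25 simulated compounds plus 2 decoys
(peaks sharing a real compound's ion pair at a distant RI), all separated
correctly. Species identity explains ~89 % of blend variation — blends are
strongly species-specific — while the within-species Welch contrast between
mating strategies hovers around zero across seeds (the generator plants no
strategy effect; this seed happens to sit at the edge of its sampling
noise). K_mult below 1 but highly significant reflects real phylogenetic
structure diluted by intraspecific noise.

## Command line

```sh
blendevol simulate --out data --seed 1                  # synthetic study + truth
blendevol align   --peaks data/peaks.csv --ladders data/ladders.csv \
                  --meta data/metadata.csv --out out/align
blendevol analyze --matrix out/align/matrix.tsv --meta data/metadata.csv --out out/an
blendevol phylo   --matrix out/align/matrix.tsv --meta data/metadata.csv \
                  --tree data/tree.nwk --test kmult --out out/phylo
blendevol run     --config config.yaml --out out       # whole pipeline + manifest
```

Exit codes: 0 ok, 2 validation error, 3 degenerate statistic.

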