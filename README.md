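# ampdyn

Temporal dynamics of amplicon-surveyed microbial communities, built around
one question: **does PCR primer bias distort what a 16S rRNA survey says
about community *dynamics*, or only what it says about composition?**

Every primer pair amplifies some templates better than others, so two
surveys of the same activated-sludge basin with different 16S variable
regions report different relative abundances — sometimes drastically so for
individual taxa.  Whether the *temporal* conclusions (turnover rate,
similarity decay, month-to-month change, environmental drivers) survive
that distortion is an empirical question.  `ampdyn` provides the analysis
stack to ask it of real OTU tables, and a synthetic community generator
that encodes the causal setup — one latent community observed through two
bias vectors — so the robustness claim is testable end to end without any
sequencing data.

Intended users: microbial ecologists and bioinformaticians working with
community time series (wastewater treatment, bioreactors, other engineered
or natural systems) who need diversity, ordination and turnover statistics
with explicit, permutation-based inference.

## What it computes

- **Alpha diversity** on subsamples drawn without replacement at a fixed
  depth: observed richness S_obs, Shannon H = −Σ pᵢ ln pᵢ, Monte-Carlo
  rarefaction curves with the exact hypergeometric expectation
  E[S] = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)] as oracle, and a paired-by-time-point
  comparison between primer regions.
- **Beta diversity**: Bray-Curtis, unweighted UniFrac, and normalized
  weighted UniFrac (all on [0, 1]) from a rooted branch-length tree.
- **Ordination & inference**: PCoA, NMDS (Kruskal stress-1 via SMACOF +
  isotonic regression), Procrustes/PROTEST, Mantel, and CAP (distance-based
  RDA) with ANOVA-like permutation tests on pseudo-F.
- **Temporal dynamics**: the temporal core (taxa present at every time
  point) and order-level shared cores; moving-window series of consecutive
  month dissimilarities; similarity-decay regressions log₁₀(1−D) ~ Δt with
  slope comparison by Student's t; and the taxa–time relationship
  S = cT^w, whose exponent w is the taxon replacement rate.
- **FISH biovolume**: probe/DAPI pixel ratios per field of view, averaged
  per sample — a sequencing-independent abundance estimate to correlate
  against amplicon relative abundances.
- **Synthetic communities**: seasonal AR(1) log-abundance dynamics, a
  stable core holding two thirds of abundance, windowed transient taxa, a
  bloom taxon with region-dependent (×12) amplification, per-region bias
  vectors, PCR-replicate jitter and multinomial read sampling at 2125
  reads/sample.

OTU tables are tab-separated with taxa as rows and samples as columns
(first column taxon id, header row of sample ids).  Time points are
1-based consecutive months.  See `docs/methods.md` for the models,
parameter defaults and their rationale.

## Worked example

Simulate the two-region design and ask whether the regions agree on the
dynamics while disagreeing on the bloom taxon's abundance:

```python
import numpy as np
from scipy import stats
from ampdyn import SyntheticParams, simulate_experiment, distance_matrix, mantel
from ampdyn.dynamics import moving_window, taxa_time_relationship, mean_w
from ampdyn.io_formats import DistanceMatrix

exp = simulate_experiment(SyntheticParams(seed=1))
D = {}
for region in ("V1V3", "V4"):
    table = exp.tables[region]
    D[region] = distance_matrix(table.select_samples(sorted(table.sample_ids)),
                                "bray_curtis")

matched = DistanceMatrix(D["V1V3"].sample_ids, D["V4"].values, "bray_curtis")
res = mantel(D["V1V3"], matched, n_perm=999, seed=1)
print(f"Mantel r = {res.r:.2f}, p = {res.p:.3f}")

mw = {r: moving_window(D[r], exp.design, r).means for r in D}
print(f"moving-window Pearson r = {stats.pearsonr(mw['V1V3'], mw['V4'])[0]:.2f}")

for region in D:
    w, sem = mean_w(taxa_time_relationship(exp.tables[region], exp.design, region))
    print(f"{region}: w = {w:.3f} +/- {sem:.3f}")

bloom = {r: exp.tables[r].relative_abundances()[0].reshape(12, 2).mean(axis=1)
         for r in D}
print(f"bloom abundance at month 2: "
      f"V1V3 {bloom['V1V3'][1]:.1%} vs V4 {bloom['V4'][1]:.1%}")
```

Output:

```
Mantel r = 0.93, p = 0.001
moving-window Pearson r = 0.73
V1V3: w = 0.437 +/- 0.008
V4: w = 0.436 +/- 0.004
bloom abundance at month 2: V1V3 7.2% vs V4 0.7%
```

The two regions report the bloom taxon at a ~10-fold different abundance,
yet their distance matrices correlate at r = 0.93, their month-to-month
change profiles at r = 0.73, and both recover the same replacement rate
w ≈ 0.44: composition is biased, dynamics are not.

The same stages are available from a shell via the `ampdyn` CLI
(`simulate`, `alpha`, `beta`, `ordinate`, `dynamics`, `fish`, `report`);
every subcommand takes `--seed`, `--config`, `--out-dir` and `--log-level`,
and `report` emits the full two-region comparison as JSON.

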