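# Methods

This note documents the statistical models behind `sharedzotu`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions used throughout.

## The occurrence framework

All inference runs on a binary ZOTU × individual occurrence matrix with a
host-species partition of the individuals. Matrix orientation is fixed:
ZOTUs are rows, samples are columns, so "row sums" always means per-ZOTU
incidence (number of individuals occupied) and "column sums" per-individual
richness. Presence is strictly `count > 0`; every count threshold lives in
the QC cascade, never in the binarization, so the two concerns cannot
interact. Read abundances are used only for core-ZOTU ranking and
class-composition summaries — presence/absence is the conservative choice
when half the count variation between technical replicates is noise (the
generator reproduces exactly that noise level, see below).

## QC cascade

Stage order: control filter → taxonomy collapse → replicate filter →
tag-jump filter → target filter → rare filter. Conventions, each chosen once
and asserted by tests:

* **Boundaries are strict `<` everywhere; ties survive.** A cell equal to
  the control level, to 0.05% of its sample total, or to 20 reads is kept.
* **Control aggregation** is the maximum over all extraction and PCR
  controls (most conservative; a `sum` alternative is available). With no
  controls present the stage is skipped with a warning rather than failing.
* **Tag-jump denominators are frozen at stage entry.** "Proportion of the
  total reads in one sample" is read as a fixed per-sample total, not a
  running total that shrinks as cells are removed. Because the rare filter
  lowers the totals a later tag-jump stage would see, the two filters do
  not commute; the suite pins the chosen order (tag-jump before rare) with
  a fixture on which the orders differ. The tag-jump stage can optionally
  run before replicate merging (`tag_jump_before_replicate`); the default
  applies it to summed per-individual totals, matching the stated stage
  order.
* **Taxonomy collapse** merges rows with an identical full lineage
  (domain→genus, the deepest rank the reference database provides); rows
  unassigned at every rank have no taxonomic identity and stay distinct.
  Only groups that actually merge adopt the lineage string as their id.
* **Stages zero cells; empty rows/columns are dropped only at cascade
  end**, so the audit report can attribute removed occurrences and retained
  reads to individual stages. Retained reads are non-increasing by
  construction (collapse conserves them).

## Richness extrapolation

Incidence-based estimators with the small-sample correction `A = (N−1)/N`:

* Chao2: `S_obs + A·Q1²/(2Q2)` when `Q2 > 0`, else `S_obs + A·Q1(Q1−1)/2`,
  where `Q1`, `Q2` count ZOTUs seen in exactly one or two individuals of
  the focal species. The variance uses the standard two-branch formula
  (`G = Q1/Q2`): `Q2·A·G²(1/2 + A·G(1 + G/4))` for `Q2 > 0`, and the
  `Q2 = 0` small-sample variant otherwise. A flag switches to the classic
  uncorrected form (`A = 1`).
* First-order jackknife: `S_obs + Q1·(N−1)/N`, with the variance computed
  from the per-individual counts of singleton ZOTUs,
  `((N−1)/N)·(Σ_j s_j² − Q1/N)`.

Both formulas and their SEs reproduce, to printed precision, the values of
the standard R ecology toolkit on a frozen reference matrix (see
`tests/conftest.py`). Estimator consistency is tested on simulated pools
with a log-uniform prevalence tail, where both estimators undershoot and
their absolute bias shrinks monotonically as individuals accumulate; pools
without a rare tail can make the jackknife cross from under- to
overestimation, which is why the test pool is rare-tailed.

Accumulation curves are sample-based: cumulative distinct ZOTUs over a
random ordering of individuals, averaged over 200 randomizations by
default; the mean curve equals the exhaustive average over all orderings on
enumerable cases. No curve smoothing is applied — smoothing is display-side.

## BCa bootstrap intervals

Mean incidences of unique/shared ZOTUs carry bias-corrected and accelerated
(BCa) 95% intervals, bootstrapping over ZOTUs (B = 10,000 by default).
`z0` is the normal quantile of the fraction of bootstrap means below the
point estimate, counting ties as half (this tie rule is why the routine is
implemented here; an independent library implementation agrees within
resampling error and serves as a cross-check in the tests). The
acceleration `a` is the jackknife skewness. With `z0 = a = 0` the interval
reduces to the percentile interval; an all-equal sample yields the
degenerate point interval. Calibration: 95% intervals for the mean of a
lognormal(0, 0.5) sample at n = 50 cover the truth in ≈ 0.94 of 1,000
experiments (BCa is known to undercover slightly for skewed data at this
sample size; the 0.95 ± 0.03 band holds).

## Fixed-fixed null model

Each of the `n_rand` (default 1,000) null matrices preserves both margins
exactly and is sampled **independently** (fresh fill + swaps, not a thinned
chain), which removes autocorrelation questions from the interval
estimates. The sampler:

1. builds an integer matrix with the target margins by pairing a shuffled
   multiset of column labels with the row multiset;
2. removes overfilled cells with random 2×2 moves that never increase the
   sum of squares, each anchored at a randomly chosen overfull cell (an
   implementation detail for speed, ~3 ms per draw at 400 × 40);
3. runs a burn-in of neutral checkerboard swaps (`max(200, 10·fill)`
   uniformly-proposed attempts).

Step 3 is deliberate: stopping at the first binary matrix — as the
classical quasi-swap does — leaves a measurable non-uniformity on some
margins (about 20% relative deficit for one of the five matrices with
margins (2,1,1)/(2,1,1)). The checkerboard-swap chain is symmetric and
connected on the fixed-margin binary matrices, so its stationary
distribution is uniform; the burn-in erases the residual bias. Uniformity
is verified by chi-square against exhaustive enumeration on several small
margin sets, and null means match enumeration averages on a 6×6 toy within
Monte-Carlo error. A curveball sampler (trades of unshared ZOTUs between
random pairs of individuals, burn-in `5·max(rows, cols)·ln(rows)` trades
from the observed matrix) is provided as an alternative and is
distributionally indistinguishable from quasi-swap in the tests.

Summaries per statistic (span counts `span_k` = # ZOTUs in exactly k
species, their proportions, and every Venn cell): observed value, null mean
and SD, 95% **HDCI** — the shortest contiguous window of the sorted null
sample containing at least `ceil(mass·n)` draws, width ties resolved to the
smallest lower endpoint — and an exceedance flag. Proportions and counts
flag identically because the ZOTU total is fixed under both margins; the
code asserts this rather than assuming it. ZOTUs seen in exactly one
individual are invariant under any fixed-margin randomization (a row of sum
1 always lands in one species), so matrices made only of such rows produce
degenerate HDCIs equal to the observed values — a useful exactness check.

## Community comparison

* **Sørensen dissimilarity** `(A + B − 2J)/(A + B)` (the presence/absence
  Bray–Curtis), with per-pair A, B, J accessible.
* **PERMANOVA**: `SS_total = Σ_{i<j} d²/N`, `SS_within = Σ_g Σ_{i<j∈g}
  d²/n_g`, pseudo-F with `(g−1, N−g)` degrees of freedom; p-value from
  label permutations with the add-one convention (p can never be 0). A
  single group returns R² = 0 with the test skipped; zero within-group
  dissimilarity returns pseudo-F = ∞ with R² = 1.
* **Dispersion homogeneity**: principal-coordinates embedding of the
  double-centred distance matrix keeping negative-eigenvalue axes as an
  imaginary part; each individual's distance to its **group centroid** is
  `sqrt(real² − imaginary²)` (clamped at 0 with a warning), followed by a
  one-way ANOVA F on those distances. The centroid (group mean) is used
  rather than the spatial median: it is deterministic and matches the
  reference implementation's `type="centroid"` option, whose output this
  code reproduces to printed precision; the median variant is not
  implemented. No Lingoes/Cailliez correction is applied.
* **Core ZOTUs**: ranked by overall prevalence, ties by total relative read
  abundance (RRA) descending, then lexically by id. **Class composition**:
  per-individual RRA summed by class (unassigned pooled as "unclassified"),
  averaged per species, reported in percent.

## Synthetic data generator

The generator emulates a four-species, ~40-individual survey with ~400
ZOTUs by default (a `paper_scale` constructor switches to 4 × ~46
individuals and ~1,500 ZOTUs); the scaled default keeps the full test suite
and verification script fast while preserving every structural feature the
analyses rely on. Two stages:

**Occupancy.** Core ZOTUs (120) each draw one presence probability from
U(0.05, 0.5) applied to *every* individual regardless of species — cores
are column-exchangeable, and their per-species mean incidence conditional
on detection lands in the 3–4.5 range typical of shared gut taxa.
Incidental ZOTUs (70 per species, 280 total) are placed neutrally across
all individuals at probability 1/(total individuals), zero-truncated, so
each is seen in about one individual (per-species unique mean incidence
≈ 1.05–1.3) and usually in one species. Neutral placement is a deliberate
design decision: it makes the no-effect matrix column-exchangeable, so
with no injected effect the observed sharedness falls inside the null
HDCIs — the generator matches its own null. Genuinely species-restricted
incidentals cannot satisfy that baseline: their multi-incidence rows
necessarily concentrate in one species and sit several null SDs above the
fixed-margin expectation, which is precisely the *signal* the analysis
exists to detect, so the generator reserves it for the injected effect.
`specific_excess = e > 1` adds `(e−1)·70` extra ZOTUs confined to one
designated species at within-species prevalence 3/(total individuals)
(conditional mean incidence ≈ 1.3). This designed effect produces a
single-species surfeit that the full pipeline flags (observed `span_1`
above the null HDCI) in ≥ 95% of datasets at `e = 3`, while leaving
per-species unique-ZOTU incidence within the empirically plausible range.

**Counts.** Per individual, sequencing depth is lognormal (median 40,000
reads split over two replicates); expected ZOTU shares are Dirichlet over
the present ZOTUs with concentration 3.0 for cores and 1.0 for incidentals
(cores are systematically more abundant; the exponential profile for rare
taxa keeps occurrences above the 20-read/0.05% filters at typical depths,
matching the near-lossless behaviour of the real cascade — a heavier tail
would make the QC remove an unrealistic ~18% of occurrence rows). Each
replicate is an independent realization: a per-ZOTU gamma multiplier with
CV 0.5 followed by a multinomial draw, which calibrates the median paired
|c1 − c2|/mean discrepancy to ≈ 50%. Contaminant ZOTUs appear in all
controls (Poisson mean 30) and sporadically at low counts in sample
replicates; off-target rows (plant/chloroplast lineages) carry solid counts
removable only by the taxonomy filter. Synthetic taxonomy assigns each
biological ZOTU a unique genus so that collapsing never conflates distinct
simulated ZOTUs; the collapse stage is exercised by dedicated fixtures
instead.

**What passing tests do and do not show.** The generator reproduces the
occupancy structure, replicate noise level, contamination, and the injected
surfeit — not sequence-level artefacts (chimeras, index-hopping mechanics),
nor phylogenetic correlation of prevalences, nor covariation between
abundance and prevalence beyond the core/incidental split. Success on
synthetic data therefore validates the statistical machinery and the filter
semantics, not the upstream bioinformatics.

## Reproducibility and problem sizes

Every randomized routine takes a seed; ensembles derive per-draw streams
from a `SeedSequence`, and the pipeline records all stage seeds in its
provenance block, so reruns are byte-identical. `scripts/acceptance.py`
uses: 10,000 draws for margin preservation, 60,000 for uniformity, 1,000
null draws on the enumeration toy, 200 datasets for PERMANOVA type-I
(999 permutations each), 1,000 experiments for BCa coverage (B = 1,000),
and 100 datasets × 400 null draws for surfeit recovery — sizes chosen so
Monte-Carlo error is small relative to each tolerance while the whole
script completes in minutes.

## Known limitations

* The dispersion test offers only the centroid definition; the spatial
  median variant of the reference software is not implemented.
* Richness SEs follow the reference implementation's formulas; they are
  asymptotic and can be optimistic at small N.
* The jackknife SE requires per-sample singleton counts; frequencies built
  by hand (without a matrix) report it as NaN.
* The fixed-fixed null conditions on both margins; it does not model
  abundance, and weighted (abundance-preserving) null models are out of
  scope.
* Deposited field tables are read through the column-mapping config, but
  reproducing published numbers requires the archived dataset, which is
  not bundled.
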