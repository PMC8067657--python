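# Methods

`phycobycatch` analyzes the heterotrophic bacterial "bycatch" that
accumulates in long-term enrichment cultures of the marine picocyanobacteria
*Prochlorococcus* and *Synechococcus*. Its inputs are 16S V4 amplicon
feature tables (ASVs or OTUs), a feature phylogeny, taxonomy, 96-well plate
layouts, culture metadata, and ocean transect site tables. This note
documents the models, the numerical conventions, and the design choices
made where the procedure was genuinely open.

## Decontamination model

Plate-sequenced amplicon libraries pick up two kinds of spurious signal:
PCR product bleeding between physically adjacent wells, and a diffuse
low-level background. The pipeline removes both on per-sample *relative
abundances*:

1. **Adjacency filter.** A feature's entry in well *w* is zeroed when it is
   positive and strictly less than `adjacency_ratio` (default 0.10) times
   the maximum relative abundance of the same feature in any occupied well
   adjacent to *w*. All comparisons are evaluated against the input table
   simultaneously, so the result does not depend on the order wells are
   visited. "Adjacent" defaults to the 8-neighborhood (queen moves);
   aerosol and pipetting contamination is not axis-aligned, and the
   8-neighborhood is the conservative (more removal) choice. The rook
   4-neighborhood is selectable (`adjacency_scheme="edge4"`).
2. **Abundance floor.** Entries strictly below `abundance_floor` (default
   0.002, i.e. 0.2%) are zeroed; entries exactly at the floor are kept.
   The default is calibrated by `calibrate_floor`, which sequences a mock
   community of known members and recommends the maximum relative abundance
   attained by any non-member feature.

Boundary conventions are strict `<` in both rules. Filtered tables are
**never renormalized**: renormalization would silently change other
features' pass/fail status, and all downstream presence/absence and
richness calls use the filtered values as-is.

The two filters commute on the final table whenever `adjacency_ratio < 1`:
an entry at or above the floor can only be adjacency-zeroed against an
adjacent maximum that itself exceeds the floor, so flooring first never
changes which entries survive. The test suite pins this order-independence;
the only observable order effect is which rule a removal is *attributed* to
in the filter report. The pipeline default remains adjacency → floor.

Relative abundances for filtering are computed over **all** reads,
including the cyanobacterial host, and host/organelle exclusion happens
after filtering — contamination physically involves the whole amplicon
pool, in which host reads dominate. The alternative order is supported and
logged; whether the original workflow normalized before or after host
exclusion is not documented, so the default is a package choice, not a
claim.

Host exclusion drops features whose taxonomy matches the configured host
set ({*Prochlorococcus*, *Synechococcus*}); organelle exclusion drops
features whose lineage contains "mitochondria" or "chloroplast" (case
insensitive). Host-read normalization divides each heterotroph count by
the sample's host-assigned reads; samples with zero host reads are emitted
as missing rather than infinite.

## OTU clustering

To merge features within and across datasets whose amplicons span nested
primer regions, sequences are primer-trimmed, optionally truncated to the
common minimum length, dereplicated (representative = lexicographically
smallest id, abundances summed), and clustered by greedy first-fit centroid
clustering at 97% identity: sequences are visited in decreasing abundance
(ties: longer first, then lexicographic id) and join the first centroid —
in founding order — with identity at or above the threshold, else found a
new centroid. First-fit (not best-fit) is the convention of the standard
centroid clustering tools and is pinned by a regression test.

Pairwise identity is computed from a global alignment with free end gaps
(match +5, mismatch −4, gap open −10, gap extend −1) as matching columns
over alignment columns **excluding terminal-gap columns**, so a short
amplicon nested inside a longer one can reach identity 1. The exact
identity formula of the upstream tools is not published alongside the
threshold, so two alternatives (include terminal gaps; divide by the
shorter sequence length) are selectable. `N` never counts as a match.

## Beta diversity

**Unweighted UniFrac** is computed by explicit branch enumeration: for a
sample pair, the distance is the total length of branches whose subtree
contains tips present in exactly one sample, divided by the total length of
branches subtending tips present in either. Presence means value > 0
*after* decontamination. The root's own stem is excluded from both sums —
it subtends every tip and can never be unique; conventions differ here, so
the choice is pinned by test. A pair of two empty communities has no
defined distance and is emitted as missing.

**PCoA** double-centers −d²/2 (Gower) and eigendecomposes; axes with
negative eigenvalues (non-Euclidean distance sets) are retained as a
separate imaginary block so squared distances reconstruct exactly as
(positive-block squared distance) − (negative-block squared distance).

**Ward clustering** runs Lance–Williams updates on squared distances and
reports merge heights on the original distance scale, matching the
standard linkage implementations; ties merge the lexicographically
smallest pair of cluster labels (a cluster is labeled by its smallest
member), making the dendrogram deterministic.

**Rarefaction richness** is the mean, over `reps` (default 100) seeded
without-replacement subsamples of size `depth` (default: minimum sample
total), of the number of distinct features observed. The closed-form
hypergeometric expectation E[S] = Σᵢ (1 − C(N−Nᵢ,d)/C(N,d)) is the oracle
in tests. Neither the depth nor the replicate count of the original
analysis is documented, so rarefied richness values are not treated as
reproduction targets.

## Permutation statistics

All permutation p-values use the add-one convention
p = (1 + #{null ≥ observed}) / (1 + n_perm), so no finite test reports 0;
the default permutation count is 1000.

- **PERMANOVA**: SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g,
  pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)); labels permuted. For
  Euclidean 1-D input the statistic equals the classical one-way ANOVA F
  (verified to 1e-8). Groupings with zero within-group variation are
  flagged degenerate rather than reported.
- **Beta-dispersion (PERMDISP)**: samples embedded by PCoA with the
  imaginary block kept; dispersion of sample i is
  √(max(0, d₊² − d₋²)) to its group centroid across the two blocks; the
  group effect is a one-way ANOVA F on these dispersions with a
  label-permutation p. Pairwise post-hoc tests are provided **both** as
  pairwise PERMANOVA and pairwise dispersion tests (the original report is
  ambiguous about which was run), Bonferroni-adjusted by the number of
  pairs.
- **Indicator species (IndVal)** on presence/absence: for feature f and
  group g, specificity A = (I_g/n_g)/Σ_k(I_k/n_k) (group-size equalized),
  fidelity B = I_g/n_g, statistic = max_g √(A·B); label-permutation p per
  feature; Bonferroni (default), Holm or BH across features. The
  group-size-equalized variant is the default family of the standard
  indicator-analysis package; raw-incidence alternatives were deliberately
  not implemented to keep one pinned definition.
- **Fisher's exact test** enumerates the hypergeometric distribution
  directly (two-sided: sum of probabilities ≤ the observed table's, with
  1e-7 relative tie slack); the odds ratio is the sample (ad)/(bc).
- **Spearman's rho** is Pearson on mid-ranks (tie-corrected); the p-value
  is the exact permutation fraction for n ≤ 9 and the t approximation with
  n−2 df above that.
- **Goodman–Kruskal τ(x→y)** is the proportional reduction in Gini
  variation of y given x; τ = 1 when y is a function of x (e.g. clades
  nested within ecotypes), and it is asymmetric by construction.

Multi-factor marginal PERMANOVA (interaction testing) is out of scope: the
sums-of-squares decomposition used upstream is package-specific and not
restated in a reproducible form, so only univariate and two-group
restricted tests are provided.

## Culture-versus-ocean analyses

Per-site OTU relative abundance is OTU reads / (total − host reads); sites
with no non-host reads are missing. Occupancy (fraction of sites with
abundance above a detection floor, default 0) classifies each OTU as
Cosmopolitan (≥ 0.75), Sparse (≤ 0.25) or Intermediate. The cut points are
package defaults — the source labels are qualitative — and are reported
alongside every classification. Host coupling is the Spearman correlation
of an OTU's site fractions with the combined host read fraction, zeros
ranking at the bottom as ties. The depth-partition test pools OTUs
detected strictly below 200 m (the epipelagic boundary) against those at
or above it — a site at exactly 200 m counts as "above" — and tests
shared-with-culture membership with Fisher's exact test.

## Synthetic data

The simulators generate data with the structure the analysis assumes, plus
ground truth. They are pure functions of (params, seed).

- **Plates** (`simulate_plate`): up to 96 wells in row-major order, each
  with one host feature at a fraction drawn uniformly from (0.5, 0.95) —
  sequencing of these cultures is dominated by host reads, though exact
  fractions vary and are configurable — plus 4–12 heterotrophs drawn from
  a shared pool of 60, with log-normal (σ = 1.5) within-well proportions
  producing the few-dominant/many-rare structure typical of these
  communities. Each ordered adjacent pair leaks a fraction ε ∈ [0.001,
  0.02] of the source well's whole amplicon pool into the receiver, so a
  well's expected composition is (1 − Σε)·own + Σε·neighbor. Counts are
  multinomial at depths of 50k–150k reads. The simulator's adjacency
  matches the filter's configured scheme so truth and filter are
  commensurable. The leakage model is a declared stand-in: it does not
  claim a physical mechanism (index hopping vs pipetting), and it omits
  chimeras, PCR error, and read-level noise.
- **Mock communities** (`simulate_mock`): 11 members, equimolar or
  two-fold dilution series (max/min = 2¹⁰ = 1024), three technical
  replicates, depth defaulting to 113,602 reads (the study's average
  library depth), with spurious features injected at expected relative
  abundance ≤ `contaminant_max_rel`.
- **Trees** (`simulate_tree`): random sequential-join rooted binary
  topology with Exp(1) branch lengths — a stand-in for out-of-scope
  phylogeny inference; it carries no substitution model.
- **Ocean sites** (`simulate_sites`): 500 sites with surface-weighted
  depths on 0–5000 m, OTUs split 20/30/50% into Cosmopolitan /
  Intermediate / Sparse archetypes with site-occupancy probabilities
  0.9 / 0.5 / 0.05, and one designated OTU whose abundance is coupled to
  the combined host abundance through a Gaussian copula calibrated via
  ρ_pearson = 2·sin(π·ρ_spearman/6) so the *recovered* Spearman statistic
  targets the requested value directly.

Because the simulators realize exactly the contamination and coupling
models the filters and statistics assume, passing recovery tests show
internal correctness and calibration — not that real sequencing artifacts
follow these models.

## Test and calibration conventions

Permutation-test calibration is checked on null simulations (continuous
Euclidean data, random labels): 500 datasets, 199 permutations each, with
the rejection rate at α = 0.05 required to sit within 3 binomial standard
errors of 0.05. For the indicator statistic the null groups use unequal
sizes (9/12/15): with equal group sizes the presence/absence statistic
collapses to a handful of distinct values and the permutation test becomes
far more conservative than nominal, which would test the data design
rather than the implementation. Oracle comparisons use independent
implementations: a cell-by-cell double loop for the adjacency filter,
exact rational hypergeometric enumeration for Fisher, the closed-form
hypergeometric expectation for rarefaction, classical ANOVA for the
PERMANOVA statistic, scipy's Ward linkage for merge heights, and
scikit-bio's UniFrac for the distance matrix.

## Known limitations

- Greedy clustering recomputes full pairwise alignments; there is no k-mer
  prefilter, so it is intended for the hundreds-of-features scale of
  culture datasets, not metagenome-scale inputs.
- The exact-permutation Spearman branch enumerates all n! orderings and is
  only used for n ≤ 9.
- `beta_dispersion` permutes the fixed distances-to-centroid; it does not
  re-embed under each permutation.
- Distribution-class cut points and the site detection floor are
  conventions, not estimates; conclusions about occupancy classes move
  with them.
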