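# phycobycatch

Long-term enrichment cultures of the marine picocyanobacteria
*Prochlorococcus* and *Synechococcus* are never really monocultures: they
carry a community of heterotrophic bacteria — the "bycatch" — that feeds on
host exudates and shapes culture behavior. Characterizing that community
from 16S amplicon data is dominated by two nuisance signals: PCR products
bleeding between adjacent wells of the sequencing plate, and a diffuse
low-abundance background. `phycobycatch` implements the full analysis
pathway for this problem, for microbial ecologists working with
plate-sequenced culture collections:

- **Decontamination**: a plate-adjacency filter (zero a feature in a well
  when its relative abundance is < 10% of its maximum in an adjacent well)
  and a mock-community-calibrated relative-abundance floor (0.2%), with
  host-read exclusion and host normalization.
- **Feature merging**: primer/length trimming, dereplication, and greedy
  first-fit centroid clustering at 97% identity with alignment-based
  pairwise identity, plus cross-dataset shared-OTU counts.
- **Diversity**: threshold richness, rarefaction richness, unweighted
  UniFrac (u = unshared branch length / total branch length), PCoA with the
  negative-eigenvalue block retained, Ward hierarchical clustering.
- **Statistics**: PERMANOVA (pseudo-F on squared distances, permutation p),
  beta-dispersion (PERMDISP) with pairwise post-hocs, indicator-value
  analysis (IndVal, stat = max_g √(A_g·B_g)) on presence/absence, Fisher's
  exact test by hypergeometric enumeration, tie-corrected Spearman,
  Goodman–Kruskal τ.
- **Biogeography**: per-ocean-site OTU abundance normalized to non-host
  reads, Cosmopolitan/Intermediate/Sparse occupancy classes, host-coupled
  abundance correlation, and the above/below-200 m shared-OTU test.
- **Simulators** for plates with cross-well leakage, mock dilution series,
  feature phylogenies, and ocean transect site tables, each with ground
  truth for filter-performance and parameter-recovery testing.

All permutation tests use p = (1 + #{null ≥ observed}) / (1 + n_perm).
See `docs/methods.md` for models, conventions and limitations.

## Worked example

Simulate a 48-well plate of enrichment cultures with cross-well leakage,
decontaminate it, and test whether heterotroph community composition
differs between host genera:

```python
import phycobycatch as pb

params = pb.PlateSimParams(n_wells=48, seed=7)
counts, layout, taxonomy, truth = pb.simulate_plate(params)

filtered, report = pb.decontaminate(counts, layout)
print(f"zeroed {len(report)} of {(counts.counts > 0).sum()} nonzero entries")

het, removed = pb.exclude_features(counts, taxonomy, which="host")
het_rel = pb.RelAbundTable(filtered.data[het.feature_ids])
richness = pb.richness_at_threshold(het_rel, threshold=0.002)
print(f"median heterotroph richness: {richness.median():.0f} "
      f"(range {richness.min()}-{richness.max()})")

tree = pb.simulate_tree(het.feature_ids, seed=7)
dm = pb.unweighted_unifrac(tree, pb.presence_sets(het_rel))

host_genus = {s: taxonomy.rank_of(next(f for f in truth.true_members[s]
                                       if taxonomy.is_host[f]), "genus")
              for s in counts.sample_ids}
result = pb.permanova(dm, pb.Grouping(host_genus), n_perm=999, seed=7)
print(f"PERMANOVA by host genus: pseudo-F = {result.statistic:.2f}, "
      f"p = {result.p_value:.3f}")
```

Output:

```
zeroed 1674 of 2032 nonzero entries
median heterotroph richness: 6 (range 1-12)
PERMANOVA by host genus: pseudo-F = 1.11, p = 0.334
```

Most nonzero entries in the raw table are sub-threshold leakage or
background and are zeroed; each well retains a handful of genuine
heterotrophs (median 6 above the 0.2% floor). Because the simulator
assigns heterotrophs to wells independently of host genus, PERMANOVA
correctly finds no composition difference between *Prochlorococcus*- and
*Synechococcus*-hosted communities (p ≈ 0.33).

The same pathways are exposed on the command line:

```sh
phycobycatch --seed 7 --out-dir sim simulate plate
phycobycatch --out-dir run decontam --counts sim/counts.tsv \
    --layout sim/plate.csv --taxonomy sim/taxonomy.tsv
phycobycatch --out-dir run diversity --counts sim/counts.tsv --metric richness
phycobycatch --out-dir run stats fisher --table 5,0,0,5
```

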