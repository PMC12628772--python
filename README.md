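# nitrilink

Link microbial community structure to nitrification performance in
activated-sludge systems.  The package implements, as a tested and
reusable pipeline, the full analysis chain for asking *how much of a
process rate is explained by a functional guild, by the taxa associated
with it, and by the community at large*:

1. **Synthetic community generator** (`nitrilink.synth`) — two-period
   AR(1) environment series, a samples-by-taxa multinomial count table with
   a planted nitrifier guild, taxa correlated with the guild at
   controllable strengths, independent noise taxa, and a nitrification-rate
   series driven by the associated taxa.  Ground truth is exported so the
   whole chain can be verified by parameter recovery.
2. **K-mer re-clustering** (`nitrilink.ktu`) — ASVs embedded as
   tetranucleotide profiles, clustered with classical PAM (BUILD + SWAP),
   cluster number selected by mean silhouette width, counts aggregated to
   medoid-represented units.
3. **Diversity** (`nitrilink.diversity`) — repeated rarefaction without
   replacement (averaged over replicates), richness / Shannon / Simpson,
   Bray-Curtis dissimilarity.
4. **Compositional correlation** (`nitrilink.sparcc`) — SparCC-style
   inference from first principles: Dirichlet-posterior fraction draws,
   log-ratio variance matrices, basis-variance solves under the sparsity
   assumption with iterative strong-pair exclusion, and permutation
   p-values with the add-one estimator.
5. **Subcommunities** (`nitrilink.subcommunity`) — nitrifier selection by
   gene flags AND genus membership, association-filtered subcommunities
   across a cutoff sweep (nested by construction), and per-cutoff core sets
   as the intersection across operating periods.
6. **Process performance** (`nitrilink.performance`) — nitrate production /
   efficiency / rate arithmetic, qPCR copy-number normalization to cells,
   Shapiro-Wilk-gated t-test vs Wilcoxon between-period comparisons,
   Spearman screens.
7. **Statistical core** (`nitrilink.link`) — PCoA, standardized multiple
   linear regression of the rate on composition axes or alpha metrics per
   community slice and cutoff, time-lag variants, random-forest
   out-of-bag permutation importance, and db-RDA with forward AIC selection
   and hierarchical partitioning.

## CLI

```sh
nitrilink simulate --config sim.json --out data/       # synthetic dataset
nitrilink link --in data/ --out results/ --config pipe.json
nitrilink report --in results/
```

Other subcommands: `ktu`, `diversity`, `network`, `subcommunity`,
`performance`.  Every run writes a `run_manifest.json` with the resolved
configuration and library versions; all writers are atomic and
deterministic (lexicographic taxon order, chronological samples).

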