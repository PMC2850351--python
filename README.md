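# taxenv

Tools for studying how prokaryotic taxa distribute across a hierarchical
classification of environments, starting from 16S rDNA sequence sets.

Environmental 16S surveys produce, for each sampling experiment, a set of
sequences from whatever organisms were present. Pooling many such samples
and labelling each with a nested habitat classification (5 supertypes,
20 types, 46 subtypes — e.g. Host-associated > Gastrointestinal tract >
Cattle) makes it possible to ask which taxa are environmental
*specialists*, which are *cosmopolitan*, and which environments select
most strongly on community composition. `taxenv` implements that analysis
end to end for microbial ecologists:

- **seqprep** — length filtering, 100% deduplication of identical
  genotypes, greedy incremental clustering into OTUs at 97% identity, and
  removal of undersized samples (fewer than 5 sequences).
- **taxonomy** — consumption of external classifier calls (confidence
  > 80%) and similarity-search hit tables (best average bit-score over
  the five best hits per taxon, with a margin over the runner-up), and a
  consensus taxon per OTU: the deepest rank at which exactly one taxon
  covers ≥ 25% of the OTU's sequences, for OTUs with more than five
  members.
- **community** — the environment hierarchy, sample labels, and the
  taxa × environment matrix `Y_ij` of distinct-OTU counts, with expected
  counts under independence `E_ij = row_i · col_j / total` and
  per-sample size normalization.
- **diversity** — specificity (≥ 90% of a taxon's (OTU, sample)
  observations in one environment), cosmopolitanism (≥ 5 observations in
  ≥ 90% of environments), Hill numbers `N0, N1, N2`, and collector's
  curves by sampling pooled environment metasamples without replacement.
- **affinity** — the core statistical model: a Bayesian hierarchical
  Poisson model

  ```
  Y_ij ~ Poisson(λ_ij · E_ij),   log λ_ij = α + θ_i + γ_j + ν_ij
  ```

  with normal priors on the main effects and a two-component normal
  mixture on the interactions ν_ij (a narrow noise component and a wide
  signal component). λ_ij > 1 means taxon i is over-represented in
  environment j (affinity); λ_ij < 1 means under-presence. Inference is
  by a vectorized Metropolis-within-Gibbs sampler; environments are then
  clustered hierarchically on log posterior-median affinities.
- **ordination** — correspondence analysis of the size-normalized matrix
  with optional detrending by segments (DCA-style arch removal).
- **synthetic** — generators for all of the above with known ground
  truth: sequence sets with planted OTU identity structure, sample
  tables with planted specialist/cosmopolitan/background taxa, and
  community matrices drawn from the affinity model itself.

## Worked example

Simulate a 20 taxa × 6 environment community matrix with one cell
planted at a three-fold over-representation (ν = log 3), and fit the
affinity model:

```python
import numpy as np
from taxenv import affinity, community, synthetic

truth = synthetic.random_truth(
    20, 6, signal_sd=1.0, signal_fraction=0.1,
    planted_cells={(3, 2): np.log(3.0)}, seed=8,
)
matrix, _ = synthetic.generate_community_matrix(20, 6, truth, 50.0, seed=9)
expected = community.expected_counts(matrix)
post = affinity.fit(matrix, expected, chains=4, iterations=4000,
                    burn_in=2000, seed=10)
print(post.summary_table().query(
    "taxon == 'taxon003' and environment == 'env02'").to_string(index=False))
```

```
   taxon environment  lambda_median  prob_gt1     flag
taxon003       env02       2.497619       1.0 affinity
```

The planted cell is recovered with a posterior median affinity of ≈ 2.5
(truth 3.0, shrunk toward 1 by the mixture prior) and is flagged as an
affinity because the posterior probability of λ > 1 exceeds 0.95.
`post.diagnostics` reports effective sample sizes and split-chain R-hat
(all ≤ 1.02 here); `affinity.cluster_environments(post).to_newick()`
exports the environment dendrogram.

The same pipeline runs from the shell on files:

```bash
taxenv run-all --config config.yaml        # simulate → ... → ordinate
taxenv affinity --matrix community_matrix.tsv --out-dir results/
```

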