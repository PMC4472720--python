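# wsbinning

Bootstrap-thresholded gene-tree binning for coalescent-based species-tree
estimation, end to end: pairwise compatibility testing under a support
threshold, the incompatibility graph and its clique-seeded balanced greedy
coloring, supergene assembly with partition maps, weighted/unweighted bin
outputs, and everything needed to exercise the pipelines at desk scale —
multispecies-coalescent (MSC) simulation, GTR+Γ sequence simulation, NJ/JC
gene-tree estimation with site bootstrapping, greedy consensus, the R*
(plurality-triplet + BUILD) summary method, multi-locus bootstrapping, and
evaluation metrics (missing-branch rate, branch-length ratios, per-triplet
Jensen–Shannon divergence, edge-quality curves).

## Layout

| module | contents |
|---|---|
| `wsbinning.treeio` | support-annotated Newick I/O, bipartitions, RF distance, collapsing, rerooting, alignments |
| `wsbinning.binning` | threshold compatibility, incompatibility graph, seed clique, balanced coloring, weighted/unweighted outputs |
| `wsbinning.supergene` | per-bin concatenation, partition files, exact JC69 partitioned/unpartitioned ML (n ≤ 8), external RAxML-style adapter |
| `wsbinning.simulate` | MSC gene-tree simulation, GTR+Γ sequence simulation, the 15-taxon caterpillar preset, discordance |
| `wsbinning.estimate` | JC distances, neighbor joining, site bootstrapping with support annotation |
| `wsbinning.summarize` | greedy consensus, triplet distributions, R* supertrees, MLBS orchestration |
| `wsbinning.metrics` | FN rate, branch-length ratios, JS divergence + ECDF, edge-quality curves |
| `wsbinning.cli` | `wsbin` command-line pipelines |

## CLI

```sh
# simulate a caterpillar dataset (species tree, MSC gene trees, JC sequences)
wsbin simulate --taxa 15 --genes 100 --sites 100 --seed 1 --out data/

# estimate NJ gene trees with bootstrap supports
wsbin estimate --alignments data/alignments --bootstrap 100 --seed 1 --out est/

# bin gene trees at a support threshold, optionally writing supergene alignments
wsbin bin --gene-trees est/gene_trees.nwk --threshold 50 \
          --alignments data/alignments --out bins/

# full pipeline (weighted binning, R* summary, MLBS consensus)
wsbin run --alignments data/alignments --threshold 75 --bootstrap 20 \
          --weighting weighted --summary rstar --outgroup s15 --seed 1 --out run/

# evaluate an estimate against the truth
wsbin eval --true-tree data/species.nwk --est-tree run/species_tree.nwk
```

Exit codes: 0 success, 1 I/O failure, 2 validation failure.

## Conventions

- Bootstrap supports live on internal edges on a 0–100 scale; a missing
  support is `None`, never 0. Newick supports default to RAxML-style
  internal-node labels; a branch-comment convention is also accepted.
- A conflict between two gene trees requires both conflicting branches to
  have support ≥ B; equivalently, collapsing removes edges with support
  strictly below B.
- Species-tree branch lengths are standard coalescent units (2N
  generations; k lineages coalesce at rate k(k−1)/2 per unit). The
  15-taxon preset (`fifteen_taxon_model`) encodes θ = 0.05 with internal
  branches of 0.005 expected substitutions, i.e. 0.2 units per branch.
- The in-house exact ML solver is JC69-only and exhaustive (n ≤ 8);
  anything bigger goes through the external adapter.
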