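# cdvx

Condition-specific co-expression analysis for bulk expression compendia.

Large RNA-seq compendia mix many biological conditions, and a single
global co-expression network blurs interactions that only exist in some
of them. `cdvx` implements a workflow that (1) partitions samples into
condition clusters by k-means with silhouette-based selection of k,
(2) builds weighted co-expression modules once globally and once per
cluster, (3) scores every gene's **GMC** (gene–module consistency: the
Pearson correlation between the gene and its module eigengene) and
**CDV** (correlation difference value: cluster GMC minus the gene's
correlation with its global-module eigengene restricted to the cluster
samples; range −2…2), and (4) derives downstream products — metadata
annotation of clusters, partition-similarity sweeps over CDV thresholds
(Fowlkes–Mallows and adjusted mutual information), function-level
average-CDV maps, and a CDV-annotated tree-ensemble regulatory network.

A first-class synthetic-data module generates TPM compendia with planted
sample clusters, conserved and condition-specific modules, metadata and
function-bin enrichments, and a linear regulator→target network, so every
stage can be validated against known ground truth at desk scale.

## Layout

| module | contents |
| --- | --- |
| `cdvx.synthetic` | planted-truth compendium generator |
| `cdvx.preprocess` | TPM matrix IO, mean-TPM/annotation gene filter, z-score and log2 scaling |
| `cdvx.clustering` | k-means over samples, silhouette sweep, k selection |
| `cdvx.enrichment` | hypergeometric tests (log-factorial implementation), BH FDR, group enrichment |
| `cdvx.modules` | soft threshold, TOM, tree cut, eigengenes, module merging |
| `cdvx.specificity` | GMC/CDV tables, FMS/AMIS, CDV-threshold sweep, function-CDV maps |
| `cdvx.grn` | per-target random-forest importances, weight filter, GraphML/SIF export |
| `cdvx.pipeline` | end-to-end orchestration with a checksummed run manifest |

## CLI

```bash
cdvx synth --preset default --seed 0 --out data/          # synthetic compendium
cdvx preprocess --expr data/expression.tsv --annot data/function_bins.tsv \
    --min-mean-tpm 2 --out filtered.tsv
cdvx cluster --expr filtered.tsv --sweep 2:8 --seed 1024 --out clusters.tsv
cdvx annotate --clusters clusters.tsv --metadata data/metadata.tsv \
    --alpha 0.05 --out cluster_terms.tsv
cdvx modules --expr filtered.tsv --min-size 30 --merge-height 0.25 --out-prefix mods
cdvx run config.yaml                                      # full pipeline
```

`config.yaml` holds the input paths plus every stage parameter
(`k: 4`, `seed: 1024`, `gmc_floor: 0.6`, `merge_height: 0.25`,
`min_bin_size: 100`, `min_weight: 0.06`, `alpha: 0.05`, …); see
`cdvx.pipeline.RunConfig` for the full set and defaults.

## Notes on conventions

* The gene filter keeps genes with mean TPM strictly greater than the
  threshold **and** at least one functional bin.
* k-means runs on the z-scored matrix (population sd, matching the usual
  scaler convention); module detection runs on log2(TPM+1) — the source
  workflow does not pin the network input scale, and the log transform
  stabilizes correlation estimates.
* The network is unsigned (|PCC|^β); the module-merge threshold 0.25 on
  eigengene dissimilarity corresponds to a correlation of 0.75.
* GRN edge weights are per-target normalized importances (they sum to 1
  over each target's candidate regulators), so the default 0.06 cutoff
  is interpreted on that normalized scale.
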