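# kbimpute

Cluster-then-impute genotype imputation for structured populations, with
the evaluation harness to prove it works: a silhouette-guided K-means
partition of individuals, a Li–Stephens haplotype-copying HMM run per
partition, format adapters (numeric 0/1/2 ↔ HapMap ↔ VCF), a synthetic
structured-population simulator, and downstream GWAS / genomic-prediction
validation.

## Who this is for

Anyone imputing missing genotype calls in panels with population
structure — multi-breed livestock panels, mixed landrace collections,
stratified wild populations. A pooled reference panel mixes haplotypes
from all subpopulations; individuals within a genetic subgroup share
fewer, longer haplotypes than the pooled panel, so partitioning the
panel before imputation both sharpens the reference information and
shrinks the HMM state space each individual must search.

## The model

A target individual's two chromosomes are modelled as mosaics of a
reference haplotype panel. The hidden state at marker *m* is the ordered
pair of copied haplotypes; each copy switches to a uniformly chosen
haplotype with probability *s* per marker interval (recombination
analogue) and each emitted allele is flipped with probability *e*
(mutation/error analogue). The observed unphased genotype is the sum of
the two emitted alleles. Missing genotypes get their posterior over
{0, 1, 2} from forward–backward; the imputed call is the argmax.

The full strategy: fill missing calls with the heterozygote placeholder
1, select the cluster count K by mean silhouette over k = 2..10 (K-means,
25 restarts), split individuals by cluster, impute each cluster
independently (concurrent, deterministic), and reorder the merged result
to the original taxa order. Accuracy is scored as the matching rate

    R_match = N_correct / N_total

over masked cells, and downstream utility via GWAS power/FDR/Type-I
accounting on simulated QTN phenotypes (h² = 0.75, 20 QTNs) and GBLUP
heritability h² = V_A/(V_A + V_E) plus 5-fold cross-validated prediction
accuracy (10 QTNs).

## Worked example

```python
import numpy as np
from kbimpute import (
    PopSimConfig, simulate_population, apply_mask,
    kbeagle_impute, whole_panel_impute, matching_rate,
)

# a three-breed panel: 3 subpopulations x 30 individuals, 2,000 markers
cfg = PopSimConfig(n_subpops=3, n_per_subpop=30, n_markers=2000,
                   divergence=0.3, seed=1)
sim = simulate_population(cfg)

# hide 10% of calls, then impute with and without clustering
masked, spec = apply_mask(sim.genotypes, rate=0.10, seed=2)
res = kbeagle_impute(masked, seed=3)
print("selected K:", res.info["K"], "cluster sizes:", res.info["cluster_sizes"])
print("matching rate (cluster-then-impute):", round(matching_rate(res, spec), 3))

whole = whole_panel_impute(masked, seed=3)
print("matching rate (whole panel):       ", round(matching_rate(whole, spec), 3))
```

Output:

```
selected K: 3 cluster sizes: [30, 30, 30]
matching rate (cluster-then-impute): 0.838
matching rate (whole panel):        0.834
```

The silhouette criterion recovers the three simulated breeds, and the
per-cluster panels impute 83.8% of the hidden genotypes exactly versus
83.4% for the pooled panel on this single draw; over repeated seeds the
clustered mode is consistently at least as accurate on structured data,
while on a homogeneous panel (divergence 0) the two modes are
statistically indistinguishable.

Estimator-style interfaces are available for scikit-learn workflows:
`KBeagleImputer` / `LiStephensImputer` (transformers over nan-coded
dosage matrices), `SilhouetteKMeans`, and `GBLUP` (a regressor exposing
`h2_` after `fit`).

## Command line

```bash
kbimpute simulate --subpops 3 --n-per 30 --markers 2000 --divergence 0.3 --seed 1 --out demo
kbimpute mask --rate 0.1 --seed 2 demo.numeric.txt demo.masked.txt demo.mask.json
kbimpute run --mode kbeagle --workers 4 --seed 3 demo.masked.txt demo.imputed.txt
kbimpute convert --from numeric --to vcf demo.imputed.txt demo.vcf
kbimpute cluster --seed 1 demo.numeric.txt demo.labels.tsv
kbimpute benchmark --config bench.yaml --out records.tsv
kbimpute eval-gwas --nqtn 20 --h2 0.75 --reps 60 --seed 1 demo.numeric.txt gwas.tsv
kbimpute eval-gp   --nqtn 10 --h2 0.75 --reps 30 --seed 1 demo.numeric.txt gp.tsv
```

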