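# neotrack

Tracking neoepitope-specific CD4+ T-cell clonotypes in bulk TCRβ
repertoires.

## The problem

After peptide vaccination against a tumor neoantigen (here the p30
neoepitope of B16 melanoma, a K739N mutation in Kif18b), the responding
CD4+ helper T cells can be followed by their T-cell receptors: specific
clonotypes form *convergence clusters* — groups of 4–200 clonotypes with
the same TRBV segment and equal-length CDR3 amino-acid sequences that
differ from their neighbours by a single amino acid. Given bulk TCRβ
clonotype tables from sorted Th/Treg cells (tumor-draining lymph node,
adjuvant plaque, tumor), the questions are: how much of each repertoire
is antigen-specific, and do specific clone frequencies track tumor
control?

`neotrack` implements that quantification as a reusable pipeline:

1. **Ingest** clonotype tables (AIRR Rearrangement or MiXCR export TSV);
   out-of-frame junctions are dropped, duplicate (CDR3, V) rows merged.
2. **Rarefy** every sample to a common richness (default 1000
   clonotypes) by drawing reads without replacement until the target
   number of distinct clonotypes is reached, removing sample-size bias.
3. **Match** each CDR3 against a specificity-cluster database with a
   one-amino-acid tolerance (substitution, insertion or deletion),
   ignoring the TRBV call, via a symmetric-deletion neighbourhood index
   verified by a capped Levenshtein distance.
4. **Quantify**: matched clonotype frequencies are summed per cluster
   (f_c = Σ_{i: d(CDR3_i, c) ≤ 1} f_i) and once overall (the union).
5. **Correlate** cluster frequencies with day-14 tumor volume
   (caliper formula V = a·b²/2) using Spearman rank correlation, exact
   permutation p for n ≤ 9, two-sided; significant when p < 0.05.

A synthetic cohort generator reproduces the statistical structure of
such a study — power-law clone sizes, 50× lymph-node/plaque depth ratio,
several-orders vaccinated-vs-adjuvant frequency gaps, and a
programmable rank coupling between a cluster's lymph-node frequency and
tumor volume — so the whole pipeline is testable and calibratable
without animal data.

## Worked example

```python
from neotrack import CohortConfig, simulate_cohort, quantify, MatchIndex
from neotrack import load_builtin_cluster_db, downsample, DownsampleSpec
from neotrack.stats import ClusterTumorBurdenModel

db = load_builtin_cluster_db()          # 9 synthetic p30 clusters
cohort = simulate_cohort(CohortConfig(seed=1))
index = MatchIndex(db, max_distance=1)

vaccinated = {m for m, g in cohort.groups.items() if g != "adjuvant_only"}
quants = [
    quantify(downsample(r, DownsampleSpec(seed=i)), index)
    for i, r in enumerate(cohort.repertoires)
    if r.tissue == "tdLN" and r.mouse_id in vaccinated
]
vols = {q.sample_id: cohort.volumes[q.mouse_id] for q in quants}
res = ClusterTumorBurdenModel.from_quantifications(quants, vols).fit()
print(res.summary())
```

Or the same end to end from the shell:

```bash
neotrack run --out runs/demo --seed 1
```

which prints (abridged):

```
cluster frequency vs day-14 tumor volume (Spearman):
  tdLN       C14     rho=-0.636  p=0.0001561  n=30 *significant*
  tdLN       C25     rho=+0.545  p=0.001851  n=30 *significant*
  tdLN       C26     rho=-0.243  p=0.1958  n=30
  ...
  tdLN       union   rho=+0.028  p=0.8822  n=30
```

The C14 cluster was simulated with a programmed rank coupling of −0.65
between its lymph-node frequency and tumor volume; the pipeline
recovers rho = −0.64 at n = 30 vaccinated mice and flags it under the
p < 0.05 rule. The other clusters are uncoupled; any flags they draw
(as C25 here) are the chance hits the null-calibration tests bound at
the nominal 5% rate. The run directory contains `quantification.tsv`
(samples × clusters), `matches.tsv` (every matched clonotype),
`correlations.tsv`, `group_contrast.tsv` and a provenance file.

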