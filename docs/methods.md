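# Methods

This note documents the models, defaults and numerical choices behind
`neotrack`, and what the synthetic cohort does and does not emulate.

## Quantification model

A repertoire is a multinomial sample of reads over clonotypes; the
quantity of interest for a specificity cluster *c* is the summed
frequency of all clonotypes whose CDR3 lies within one amino-acid edit
(substitution, insertion or deletion — Levenshtein distance ≤ 1) of any
cluster member, with the TRBV call deliberately ignored. Matching is
member-wise: a clonotype is specific for *c* if it is within the
tolerance of *at least one* member, not of a cluster consensus. A
clonotype matching several clusters is credited to each of them in the
per-cluster view but exactly once in the union, which keeps the union
frequency bounded by 1; per-cluster columns are therefore not additive
and the union is the quantity to use for "total specific mass".
Unmatched clusters report an exact 0 — any floor (e.g. 10⁻⁵ on
log-scale plots) is presentation-only and never enters statistics.

### Distance kernel and index

The capped Levenshtein implementation computes only a diagonal band of
half-width `cap` of the dynamic-programming table and abandons a pair
as soon as a full row exceeds the cap; strings whose lengths differ by
more than the cap are rejected outright. Lookup against a database of
*m* members uses a symmetric-deletion index: each member is stored
under itself and its single-character deletions, a query probes the
same neighbourhood of itself, and every candidate is verified with the
exact capped distance. For Levenshtein distance ≤ d the depth-d
deletion neighbourhoods of two strings always intersect, so the index
is exact, not approximate; the test suite checks hit-set equality
against a brute-force member scan, and the distance kernel against an
independent full Wagner–Fischer program and against `edlib`.

## Rarefaction

"Downsample to 1000 clonotypes" is ambiguous between read-count and
clonotype-count rarefaction. The default, `rarefy_reads_until_richness`,
permutes the read multiset uniformly and keeps the shortest prefix
containing the target number of distinct clonotypes. Any fixed-length
prefix of a uniform permutation is a simple random sample without
replacement, so clone frequencies are recovered without bias up to the
stopping rule, whose effect is below ±0.005 absolute for a 5% clone
(verified over 1000 replicate seeds). `top_n_by_count` (keep the N most
abundant, ties broken lexicographically) is provided as the
deterministic alternative; the mode used is recorded in run provenance.
Samples already at or below the target are kept and flagged
`not_downsampled` rather than discarded; an optional minimum-richness
filter (off by default) can drop them.

## Statistics

* **Tumor volume**: V = a·b²/2 (mm³) from the larger (a) and smaller
  (b) caliper dimensions; misordered arguments are swapped with a
  warning rather than silently accepted, because the formula is
  asymmetric.
* **Spearman correlation**: midranks for ties; for n ≤ 9 the two-sided
  p value is the exact permutation probability (all n! permutations of
  one rank vector, enumerated vectorially), removing the
  t-approximation error exactly where small per-tissue subsets make it
  largest; for n > 9 the usual t approximation on n − 2 degrees of
  freedom. A constant margin yields a flagged degenerate result rather
  than an exception, since an all-zero cluster column is an expected
  outcome, not an error.
* **Significance rule**: two-sided p < 0.05 per cluster, uncorrected by
  default (nine clusters are tested); a Benjamini–Hochberg toggle
  exists and its state is printed in every report.
* **Missing volumes** are handled by pairwise deletion per cluster with
  the complete-pair count reported. Tumors below a measurable size are
  a truncation the pipeline reports but does not correct. The
  small-tumor sub-range analysis is exposed as an optional volume-range
  filter (e.g. ≤ 200 mm³), off by default.
* **Group contrasts** (vaccinated vs adjuvant-only) are descriptive —
  medians, IQRs and log10 fold differences of medians with zeros
  floored at 10⁻⁵ — with no attached test, since no particular test is
  canonical for this contrast.

The correlation stage is packaged as a model/results pair
(`ClusterTumorBurdenModel.fit() → ClusterTumorBurdenResults`) so the
estimates, their p values and the summary table travel together.

## Synthetic cohort generator

Defaults encode the study conditions the pipeline is meant for:

| parameter | default | rationale |
|---|---|---|
| group sizes | 10 / 9 / 21 (adjuvant, vaccine+PBS, vaccine+aCTLA4) | study layout |
| tissues | tdLN, CFA plaque, tumor | three compartments per mouse |
| background richness | 5000 / 2500 / 3000 clonotypes | bulk sorted-cell scale |
| read depth | 300k / 6k / 30k reads | tdLN ≈ 50× plaque cell yield |
| clone-size law | power-law density exponent 2.0, log-normal noise σ = 0.5, 5% per-clone cap | heavy-tailed clonal expansions |
| CDR3 length | Gaussian 14.5 ± 1.3 on 10–20, C…F anchors | murine TCRβ CDR3 range |
| specific targets, vaccinated tdLN | means C14 0.006, C25 0.012, C26 0.005, C22 0.002, five minor clusters 0.0008; log-normal σ = 1–1.3 | ≈3% mean union mass, three dominant clusters |
| adjuvant-only tdLN/plaque | vaccinated × 10⁻³ | "several orders" gap |
| tumor tissue | comparable means in all groups, σ = 1.5 | specific clones present without vaccination |
| coupling | C14 → −0.65 (tdLN frequency vs day-14 volume) | one tumoricidal cluster |
| growth | V(t) = 2·e^{gt} mm³, g log-normal (median 0.32/day, σ = 0.25), bimodal mixture (35% slow at 0.5×) | tolerant/susceptible mouse split |
| caliper noise | 4% multiplicative on a and b, aspect ratio 1.25 | measurement error |

Per-cluster frequencies across mice are log-normal with one latent
standard-normal per cluster per mouse, shared across that mouse's
tissues (the same expanded clones seed every compartment). Specific
mass is capped at 25% per cluster and 50% per sample. The dispersion
defaults are calibrated to the printed mean (~3%) of vaccinated
lymph-node specific mass; the published per-mouse dispersion is not
available, so occasional samples reach the high-teens percent range but
the generator does not target a specific maximum.

**Coupling is programmed in rank space.** The coupled cluster's latent
z enters a Gaussian copula with Pearson parameter r = 2·sin(πρ/6), and
the copula quantile is mapped through the growth-rate mixture's inverse
CDF (bisection on the closed-form mixture CDF). Because ranks are
invariant under the monotone marginal map, the population Spearman
correlation between frequency and day-14 volume equals the programmed ρ
regardless of the growth model's shape — including the bimodal mixture —
without per-configuration recalibration. A rate-modifier
parameterisation (rate × exp(−k·z)) was considered and rejected: its
realised rank correlation depends on the noise-to-signal ratio and
would need Monte-Carlo retuning whenever any growth parameter changes.
With several coupled clusters the latents combine linearly and the
per-cluster couplings become approximate.

Spike-in counts are integers: the cluster total is
round(t/(1−T)·B) reads (B background reads, T total target mass), split
over 1–10 clonotypes by a largest-remainder rule with at least one read
each; clonotype sequences are cluster members or their exact
distance-1 variants. Background CDR3s are rejection-sampled away from
the distance-1 neighbourhood of every cluster member (the deletion-key
screen slightly over-rejects, which is harmless), so measured
frequencies differ from targets only by count rounding and, after
rarefaction, hypergeometric noise.

### Two simulation levels

`simulate_cohort(level="repertoire")` materialises every clonotype
table. `level="frequency"` runs the identical frequency, count-rounding
and tumor-growth code but skips sequence materialisation; it exists for
large calibration sweeps (hundreds of cohorts), where the matcher and
rarefier — whose fidelity is established separately by the oracle-
equivalence and spike-recovery tests, with measurement error within
±10% relative — would add cost but no information to rank-based
statistics on frequencies that vary over orders of magnitude. The
coupling-recovery calibration (200 cohorts of 60 mice at ρ = −0.65;
500 null cohorts) runs at frequency level, and a full repertoire-level
cohort of 60 mice (background richness 1500, 30k reads, rarefied to
1000) is pushed through the entire pipeline to confirm the end-to-end
estimate falls in the expected single-cohort band.

### What the generator does not emulate

Real repertoires have V/J-dependent CDR3 composition, sequencing and
PCR error structure, shared public backbones between mice, and
zero-inflation from sorting losses; the generator has none of these.
Passing tests therefore demonstrate that the pipeline's arithmetic,
matching tolerance and inference behave as specified under the study's
statistical geometry — not that any biological conclusion transfers to
a particular dataset.

## Packaged cluster database

`data/p30_clusters_synthetic.tsv` is a synthetic stand-in for the
published p30 specificity set: nine clusters (sizes 4–30) of
equal-length CDR3s connected by single substitutions, one TRBV per
cluster, with the printed public C14/C22 sequences (CASSFGRQNTLYF,
CASSFGSQNTLYF; CGARGTGNTGQLYF) embedded as real members. It is
regenerated deterministically by `simulate.build_synthetic_cluster_db`.
Clusters are mutually ≥ 3 edits apart, so one-mismatch matching can
never cross clusters. Real databases are read from TSV with a
configurable column map (default: `cdr3`, `v.segm`, `antigen.epitope`,
`cluster.id`).

## Problem sizes in the shipped checks

The calibration suite uses 10,000 random string pairs for the distance
oracle, 1,000 index/brute-force instances, 1,000 rarefaction
replicates, 100 spike-recovery seeds over targets 0.001–0.18,
200 + 500 frequency-level cohorts of 60 mice for coupling and null
calibration, and one repertoire-level 60-mouse cohort end to end; the
default simulated cohort in the examples is 40 mice × 3 tissues.

## Known limitations

* Rarefaction loads the read multiset in memory (~one int per read);
  fine to ~10⁷ reads per sample, not for unaggregated UMI-level data.
* The exact permutation branch enumerates n! permutations and is
  capped at n = 9 (≈3.6·10⁵ permutations).
* `max_distance = 2` is supported and exact but the deletion index
  grows quadratically in string length; it is not tuned for large
  databases.
* The generator's Treg mode simply scales Th frequencies by 1/2.5;
  no separate Treg clonal structure is modelled.
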