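# amyloidscan

Analysis pipeline for deep mutational scans (DMS) of amyloid-forming
peptides read out by a tripartite β-lactamase selection: a peptide of
interest (POI, canonically Aβ42) is inserted between the two domains of
TEM-1 β-lactamase via an invariant 28-residue Gly/Ser linker, so that
aggregation of the POI depletes functional β-lactamase and lowers
ampicillin resistance. Sequencing the variant library after plating at
increasing ampicillin concentrations turns survival into a per-variant
fitness score, which reflects the thermodynamic stability of the amyloid
fibril the variant forms.

The package is aimed at groups running (or simulating) such selections:
it takes amplicon reads to variant fitness scores and carries the
analysis through fibril-stability comparison, in vitro thermodynamic and
kinetic fitting, and a sequence-feature fitness predictor. A synthetic
data generator with known ground truth makes every stage testable
without any deposited dataset.

## The quantities computed

**Variant fitness.** For variant *v* at ampicillin concentration *c*,
with read count *n_v(c)*, condition total *N(c)*, library size *V* and
pseudocount *p*:

    f_v(c) = (n_v(c) + p) / (N(c) + pV)        frequency
    e_v(c) = f_v(c) / f_v(0)                   enrichment, e_v(0) = 1
    AUC_v  = trapezoid of e_v over the concentration grid
    s_v    = log2(AUC_v / AUC_WT)              fitness score

*s* is 0 for wild type in every replicate by construction; replicate
scores are averaged after the log2 transform. A misread floor estimated
from apparent substitutions in the invariant Gly/Ser linker sets the
minimum unselected-library count for a variant to be scored.

**Fibril-stability comparison.** Per-position mean fitness, inverted
(×−1) and smoothed with a five-residue running mean, is correlated
(Pearson, per structure) with per-residue free-energy contributions of
fibril structures (e.g. FoldX output on cryo-EM polymorphs, consumed as
TSV tables).

**Aggregation thermokinetics.** The critical concentration C_crit is the
x-intercept of endpoint fibril yield versus initial monomer
concentration. Aggregation traces are fitted with the standard
closed-form solution for nucleated polymerisation with secondary
nucleation, parameterised by the composite rates λ = √(2k₊kₙm₀ⁿᶜ)
(primary) and κ = √(2k₊k₂m₀ⁿ²⁺¹) (secondary); Spearman/Pearson
correlations relate fitness to log2(C_crit ratio), λ and κ.

**Prediction.** A random forest maps a length-independent encoding of
each variant sequence (site one-hots, relative position, dipeptide
composition, physicochemical means and site deltas on the
Kyte–Doolittle, Zimmerman and Chou–Fasman scales) to fitness, with
k-fold cross-validation, permutation-importance attribution, and
windowed per-position landscape prediction for arbitrary IDP sequences.

## Worked example

Simulate a scan (4,000 reads per plate, 2 replicates, 0.1% per-base
misreads), genotype the reads, and score fitness:

```sh
$ amyloidscan simulate --out-dir demo --seed 3 --depth 4000 --replicates 2 --per-base-error 0.001
wrote synthetic dataset to demo

$ amyloidscan genotype demo/reads/*.fastq --out demo/counts_called.tsv
misread threshold (linker): 10
  discarded c=0 r=1: {'premature-stop': 14, 'multi-substitution': 317}
  ...

$ amyloidscan score --counts demo/counts_called.tsv --min-count 1 \
    --out demo/fitness.tsv --heatmap demo/heatmap.csv
scored 797/798 substitutions (99.9%); centre mean=0.23 median=-0.13
  replicate Pearson (1, 2): 0.871
```

The threshold of 10 reads per linker position is the sequencing noise
floor at this depth and error rate; 797 of the 798 possible single
substitutions were callable, and the two biological replicates agree at
Pearson R = 0.87. Comparing the landscape to the generator's 21
synthetic fibril-stability profiles:

```sh
$ amyloidscan compare-stability --fitness demo/fitness.tsv \
    --profiles demo/stability_profiles.tsv --out demo/stabcorr.tsv
median Pearson R over 21 structures: 0.990
```

i.e. positions whose substitution raises fitness are the positions that
stabilise the fibril, recovered almost perfectly from a noiseless
stability model. Training the predictor on the scored landscape:

```sh
$ amyloidscan train --fitness demo/fitness.tsv --folds 5 --trees 60 \
    --model-out demo/model.joblib --report-out demo/report.json
CV R^2: mean = 0.690 (SEM 0.014), median = 0.685 over 5 folds

$ amyloidscan attribute --model demo/model.joblib --fitness demo/fitness.tsv --top 3
relative_position            0.3093 (sign +1)
delta_hydrophobicity         0.2428 (sign -1)
mean_hydrophobicity          0.1317 (sign -1)
```

The negative signs on the hydrophobicity features say that introducing
a more hydrophobic residue lowers predicted fitness — the expected
grammar of amyloid stability. Kinetic and endpoint fits on synthetic in
vitro data:

```sh
$ amyloidscan fit-kinetics --trace demo/trace.tsv
lambda = 0.3004, kappa = 1.494, rss = 0.005648

$ amyloidscan fit-ccrit --series demo/ccrit.tsv
C_crit = 0.08343 (95% CI 0.07649-0.09449), slope = 5.163, n = 6
```

recovering the planted λ = 0.3 h⁻¹, κ = 1.5 h⁻¹ and C_crit = 0.08 µM.

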