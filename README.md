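# motifstrat

Position weight matrices (PWMs) built from high-affinity binding sites
systematically miss the low-affinity transcription-factor binding sites
that many enhancers depend on. `motifstrat` implements a pipeline for
building and benchmarking *affinity-stratified* PWM ensembles from
selection-assay binding-site pools (bacterial one-hybrid style), so that
the trade-off between motif information content and detection of
low-affinity sites can be measured rather than assumed. It is aimed at
regulatory-genomics researchers working with B1H/SELEX pools, protein
binding microarray (PBM) tables, and ChIP-seq peak sets.

## What it computes

**Affinity stratification.** Every fixed-length hit in a pool is scored
by the maximum pool-wide occurrence of any of its ungapped 8-mers
(highly repeated 8-mers mark predicted high affinity), hits are binned
into quartiles of that score, and from each quartile 50 hits are
repeatedly subsampled; each subsample yields one motif via a
one-occurrence-per-sequence (OOPS) EM, giving an ensemble of PWMs per
affinity stratum.

**Relative log-likelihood (RLL) scoring.** A sequence's score under a
PWM of width *W* with column probabilities *p<sub>i,b</sub>* is

    RLL = (x − S_min) / (S_max − S_min)

where *x* = max over all sliding windows (both strands) of
Σ<sub>i</sub> log₂ *p<sub>i,b_i</sub>*, and *S*<sub>min</sub>/*S*<sub>max</sub>
are the minimum/maximum possible window scores. Sequences are padded
with `NN` on both ends; an `N` contributes 0, so partial edge matches
are scored.

**Median-AUROC benchmarking.** Each PWM is evaluated by its ability to
separate positive sequences (pool hits, bright PBM probes binned by
fluorescence rank, or trimmed ChIP peaks binned by fold enrichment) from
10 matched control sets (mononucleotide shuffles, dim-half PBM probes,
or repeat-mask-free genomic loci); the PWM's score is the median AUROC.

**Biophysical occupancy model.** The proportion of probe bound by a TF
at a site with mismatch energy *E* (natural-log units, 0 at consensus)
is modelled as

    PredictedBinding = M / (1 + e^(E − μ))

with chemical potential μ fitted by gradient descent and scaling factor
*M* pinned to the maximum observed proportion bound.

A synthetic-data module generates every input (selected pools, PBM
tables, genomes with planted sites/peaks/mask, titration tables) from a
known ground-truth motif through one shared logistic-occupancy
mechanism, so the full pipeline is testable end-to-end with known truth.

## Worked example

```python
import numpy as np
from motifstrat import *

truth = random_ground_truth_pwm(width=10, target_total_ic=12.0, seed=11)
spec = SyntheticSpec(ground_truth=truth, seed=11, mu_sel=6.0)
pool = simulate_b1h_pool(spec, n_hits=2000, hit_length=25)

table = build_kmer_table(pool, k=8)
scores = [affinity_score(h, table) for h in pool]
quartiles = assign_quartiles(scores)

for q in (1, 2, 3, 4):
    hits = [h for h, lab in zip(pool, quartiles) if lab == q]
    ens = build_pwm_ensemble(hits, group=f"Q{q}", n_sample=50,
                             replicates=5, width=10, base_seed=100 + q)
    ics = [information_content(p)[1] for p in ens.pwms]
    print(f"Q{q}: {len(hits):4d} hits, mean total IC "
          f"{np.mean(ics):.2f} bits over {len(ens)} PWMs")

emsa = simulate_emsa(spec, np.linspace(-6, 8, 20), mu_star=1.0,
                     M_star=0.8, sigma=0.05)
res = OccupancyModel(emsa["proportion_bound"], emsa["E"]).fit()
print(res.summary())
```

prints

```
Q1:  763 hits, mean total IC 6.79 bits over 5 PWMs
Q2:  428 hits, mean total IC 7.79 bits over 5 PWMs
Q3:  426 hits, mean total IC 8.74 bits over 5 PWMs
Q4:  383 hits, mean total IC 10.06 bits over 5 PWMs

Occupancy model fit (logistic in site energy)
==============================================
n sites:              20
mu (chemical pot.):   1.078009
M  (max bound, fixed): 0.834354
RSS:                  0.0959951
R-squared:            0.9558
iterations:           269
```

The information-content gradient across quartiles is the stratification
effect: higher-affinity strata contain more repeated near-consensus
sequences and yield sharper (higher-IC) motifs. The occupancy fit
recovers the generating chemical potential (μ\* = 1.0) from a noisy
titration; μ has natural-log energy units and *M* is unitless proportion
bound.

A command-line interface mirrors the library
(`motifstrat simulate | stratify | build-ensemble | evaluate | score |
fit-occupancy | pcm2pwm | report`); every stage logs its configuration
and is byte-reproducible from its seed.

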