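# Methods

This note documents the models and procedures implemented in
`motifstrat`, the defaults they ship with, and the choices made where
the design was genuinely open.

## Matrices and pseudocounts

Matrices are (W × 4) arrays in fixed A,C,G,T column order. A position
count matrix (PCM) with column sums *n<sub>i</sub>* is converted to a
PWM with a total per-position pseudocount mass equal to *n<sub>i</sub>*.
Two arithmetics are provided because the convention differs between
labs:

- `background-split` (default): the *n<sub>i</sub>* pseudocounts are
  apportioned by the (uniform) background,
  *p<sub>i,b</sub>* = (*c<sub>i,b</sub>* + 0.25·*n<sub>i</sub>*) / (2·*n<sub>i</sub>*).
  A column observed as all-A with *n* = 10 becomes (0.625, 0.125,
  0.125, 0.125): informative columns stay informative.
- `per-base`: every base receives *n<sub>i</sub>* pseudocounts,
  *p<sub>i,b</sub>* = (*c<sub>i,b</sub>* + *n<sub>i</sub>*) / (5·*n<sub>i</sub>*).
  The same column becomes (0.4, 0.2, 0.2, 0.2): much flatter.

Neither is asserted to be "the" convention; `background-split` is the
default because it preserves the visual sharpness of published logos.

Information content is computed against a uniform background,
IC<sub>i</sub> = 2 + Σ<sub>b</sub> *p<sub>i,b</sub>* log₂ *p<sub>i,b</sub>*
bits per position, in [0, 2]. Flank trimming removes columns from the
motif ends only: width mode repeatedly drops the terminal column with
the lower IC (ties drop from the right); threshold mode drops terminal
columns below an IC cutoff. Both tie-break rules are deterministic so
ensembles are reproducible.

## RLL scoring

Log-likelihood scores and their bounds are in log₂; site energies and
the chemical potential are in natural log (the occupancy model
exponentiates base *e*). RLL is the ratio of differences and therefore
base-invariant.

Each scored sequence is padded with exactly two `N`s per side; every
width-W window of the padded sequence is scored on both strands and the
maximum kept (ties: lowest offset, then forward strand). An `N`
contributes exactly 0 to a window score. Because every concrete
log-probability is negative, an N-containing edge window can score
*above* the N-free maximum S<sub>max</sub>; the raw best score `x` is
reported as computed and the RLL ratio is clipped into [0, 1]. A
degenerate motif with S<sub>max</sub> = S<sub>min</sub> (all columns
uniform) gets RLL 1.0 with a runtime warning rather than a division by
zero.

S<sub>min</sub>/S<sub>max</sub> are always the full-width, N-free
bounds; they are not recomputed for edge windows.

## Site energies and the occupancy model

The energy of an N-free, exact-width site is the consensus-referenced
mismatch energy E = Σ<sub>i</sub> ln(max<sub>b</sub> *p<sub>i,b</sub>* /
*p<sub>i,b_i</sub>*) ≥ 0, zero exactly at a consensus. (A background
log-odds energy would differ by a per-sequence constant; since the
occupancy model is invariant to a joint shift of all energies and μ,
the choice only fixes the zero point.)

Proportion bound is modelled as M / (1 + e^(E − μ)). M is *not*
estimated: it is pinned to the maximum observed proportion bound, and
only μ is fitted, by gradient descent on the residual sum of squares
(learning rate 0.05 with step-halving backtracking, convergence when
the loss improves by < 1e-8, at most 10⁵ iterations, μ initialised at
the median energy). All three hyperparameters are arguments.

Pinning M to max(observed) has a consequence for experimental design:
unless the titration includes saturated probes (observed ≈ M), the
pinned M underestimates the true scale and the fitted μ absorbs the
error. The parameter-recovery tests therefore use an energy design that
spans saturation (E from −6 to 8 around μ\* = 1); by shift invariance
this is equivalent to any physical design whose strongest site sits
far below the chemical potential. Fits where max(observed) is well
below the plateau should be read as conditional on that M.

## 8-mer stratification and the OOPS EM

A hit's predicted-affinity score is the maximum, over its overlapping
8-mers, of that 8-mer's occurrence count in the whole pool. Counting is
forward-strand by default; `collapse_revcomp=True` pools a k-mer with
its reverse complement under one canonical key (which strand convention
a given assay warrants is left to the caller). Quartile boundaries are
the 25/50/75th linear-interpolation percentiles of the scores; a score
equal to a boundary goes to the lower quartile, so tied scores are
never split across quartiles (with heavily tied integer scores the
quartiles are therefore unequal in size — expected, not an error).

Motif discovery is a single-motif OOPS EM: each sequence contains
exactly one occurrence at a uniform-prior offset and strand; the
background is a 0-order model estimated from the input (+1 smoothing).
The E-step computes per-offset/strand posteriors from the
motif/background log-ratio; the M-step re-estimates the letter
probabilities with +0.25 pseudocount per cell. Iteration stops when the
log-likelihood improves by < 1e-6 or after 200 iterations. Each of the
5 restarts (default) is seeded from a distinct highest-count width-mer
in the input (0.7 at the seed base, 0.1 elsewhere), and the restart
with the best final log-likelihood wins. Motif width is a required
parameter (default 10); no width search is performed — a deliberate
simplification relative to motif discovers that optimise width
internally.

Ensembles: replicate *r* of a stratum samples `n_sample` (default 50)
hits without replacement with seed `base_seed + r` (with replacement
only behind an explicit flag, for pools smaller than the sample), runs
the EM, and records seed plus sampled indices, so an ensemble is a pure
function of (base_seed, config).

## Evaluation

AUROC uses the rank-sum U statistic with half-credit for ties. Every
evaluation pairs positives with 10 control sets matched in count and
per-sequence length; the PWM's score is the median of the 10 AUROCs.

Controls: (1) mononucleotide shuffles — per-sequence letter
permutations, preserving composition exactly; (2) PBM controls — draws
without replacement from the dimmest 50% of probes; (3) genomic
controls — uniform random 100-bp loci rejected if they overlap any peak
or mask interval.

PBM probes are ranked by fluorescence descending and binned at
fractions 0.25% / 0.5% / 1% / 2.5% / 5% / 10% with ceiling boundaries
(1000 probes put 3 in the top bin). The default spans are disjoint
("top 5%–2.5%"); the overlapping "top 5%–1%" span that circulates in
some bin specifications is available behind a flag but not the default,
since disjointness is required for a valid ordered binning.

ChIP peaks are ranked by fold enrichment (ties broken by genomic
order), the top 1000 kept, each trimmed to the central 100 bp
(centre = floor((start+end)/2), interval [c−50, c+50)), then split into
equal-count enrichment bins, strongest first.

Group comparisons: Kruskal–Wallis across ensembles, then all pairwise
two-sided Mann–Whitney U tests with Bonferroni multiplication by the
number of pairs (capped at 1). Exact U p-values are used when both
groups have ≤ 20 values and no ties span the pair; otherwise the
normal approximation with tie correction.

## Synthetic data

One mechanism — logistic occupancy 1/(1 + e^(E − μ)) of a site with
mismatch energy E — drives every generator, keeping the ground truth
coherent across assays:

- **Ground-truth motif**: per-column Dirichlet draws whose
  concentration is bisected (on a fixed uniform-variate block, via
  gamma quantiles) until total IC is within 5% of target. Defaults:
  width 10, 12 bits.
- **B1H pool**: background sequences accepted with probability equal to
  the occupancy of their best window at selection stringency μ_sel
  (default 6, natural-log units; smaller is more stringent). Default
  pool 2000 hits of 25 nt.
- **PBM table**: fluorescence = α · (total occupancy over all windows,
  both strands) · e^ε with ε ~ N(0, σ²), σ = 0.2, 4000 probes of 36 nt
  (array-like probe lengths; 4000 keeps the smallest bin ≥ 10 probes).
  Multiplicative log-normal noise keeps fluorescence positive. Note
  that fluorescence aggregates *all* windows while RLL takes the best
  one, so their rank correlation is positive but not near 1 (~0.6 at
  these settings) — the association, not its strength, is the designed
  property.
- **Genome/peaks/mask**: background genome with planted sites walked
  from the consensus toward target energies spanning [0, 8]; peaks are
  the 100-bp windows around sites; fold enrichment = β · occupancy ·
  e^ε; mask intervals are placed first and excluded from planting.
- **EMSA titration**: observed = clamp(M\*/(1 + e^(E − μ\*)) + N(0, σ²),
  0, 1) — additive truncated-normal noise, as proportions are bounded.

What the generators do *not* emulate: PCR/sequencing error, positional
biases of real arrays, chromatin accessibility, cooperative or
multi-TF binding, and the heavy-tailed 8-mer occurrence distributions
of very deep real pools. Passing tests therefore demonstrate the
pipeline's internal correctness and the direction of its effects, not
performance on any particular real dataset.

## Study-scale choices

The acceptance study runs at 2000 hits, 20 ensemble replicates per
quartile, 4000 PBM probes, and 300 positives for the shuffle
evaluation — sizes chosen so the whole study completes in minutes on a
single core while the stratification effects (IC gradient across
quartiles; intermediate-quartile AUROC advantage on dim probe bins;
widest inter-replicate variance in the bottom quartile) are already
resolved. The bottom-quartile-variance effect is the weakest of the
three and can invert for individual random draws; it is asserted at a
fixed seed.

## Known limitations

- Fixed motif width; no ZOOPS/ANR occurrence models, no gapped or
  higher-order motifs.
- μ is the only fitted occupancy parameter; joint (μ, M) estimation is
  deliberately out of scope.
- The EM maximises a pseudocount-penalised likelihood; the reported
  trace is monotone up to that penalty.
- Genomic control sampling is rejection-based and assumes peaks+mask
  leave most of the genome free; it errors rather than degrades when
  that fails.
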