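"""Affinity-stratified subsampling of binding-site pools into PWM ensembles.

The pipeline mirrors selection-assay practice for separating high- from
low-affinity binding sites without measuring affinity directly:

1. every fixed-length hit from a bacterial one-hybrid (B1H) style pool
   is decomposed into ungapped 8-mers and scored by the *maximum pool
   occurrence* of any of its 8-mers (highly repeated 8-mers mark high
   predicted affinity);
2. hits are binned into quartiles of that score;
3. from each quartile, 50 hits are repeatedly subsampled and a single
   motif is learned per subsample with a one-occurrence-per-sequence
   (OOPS) EM, yielding an ensemble of PWMs per stratum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .motif import PWM
from .scoring import encode_sequence, reverse_complement

__all__ = [
    "B1HHit",
    "PWMEnsemble",
    "build_kmer_table",
    "affinity_score",
    "assign_quartiles",
    "discover_motif_oops",
    "build_pwm_ensemble",
]


@dataclass
class B1HHit:
    """A selected fixed-length sequence with its predicted-affinity score."""

    sequence: str
    affinity_score: int | None = None
    quartile: int | None = None


@dataclass
class PWMEnsemble:
    """PWMs subsampled from one stratum, with full sampling provenance."""

    group: str
    pwms: list[PWM] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    hit_indices: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pwms)


def _kmers(seq: str, k: int):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


def build_kmer_table(
    sequences, k: int = 8, collapse_revcomp: bool = False
) -> dict[str, int]:
    """Occurrence counts of every overlapping k-mer across the pool.

    With ``collapse_revcomp`` a k-mer and its reverse complement share a
    single canonical (lexicographically smaller) key.
    """
    table: Counter[str] = Counter()
    for idx, seq in enumerate(sequences):
        if len(seq) < k:
            raise ValueError(f"hit {idx} is shorter than k={k}")
        encode_sequence(seq, allow_n=False)  # alphabet check
        for kmer in _kmers(seq.upper(), k):
            if collapse_revcomp:
                kmer = min(kmer, reverse_complement(kmer))
            table[kmer] += 1
    return dict(table)


def affinity_score(
    hit: str, table: dict[str, int], k: int = 8, collapse_revcomp: bool = False
) -> int:
    """Maximum pool occurrence over the hit's constituent k-mers."""
    best = 0
    for kmer in _kmers(hit.upper(), k):
        if collapse_revcomp:
            kmer = min(kmer, reverse_complement(kmer))
        try:
            best = max(best, table[kmer])
        except KeyError:
            raise ValueError(
                f"k-mer {kmer!r} absent from the table: hit does not belong "
                "to the pool the table was built from"
            ) from None
    return best


def assign_quartiles(scores) -> np.ndarray:
    """Quartile labels 1..4 from score percentiles (linear interpolation).

    Boundaries sit at the 25/50/75th percentiles; a score equal to a
    boundary goes to the lower quartile, so tied scores always share a
    label.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need at least 4 scores to form quartiles")
    if np.unique(scores).size < 2:
        raise ValueError("all affinity scores identical; cannot stratify")
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    labels = np.full(scores.size, 4, dtype=int)
    labels[scores <= q75] = 3
    labels[scores <= q50] = 2
    labels[scores <= q25] = 1
    return labels


# ---------------------------------------------------------------------------
# OOPS expectation-maximisation motif discovery
# ---------------------------------------------------------------------------

def _onehot_windows(codes: np.ndarray, width: int) -> np.ndarray:
    """(n_windows, width, 4) one-hot of all sliding windows of one sequence."""
    win = np.lib.stride_tricks.sliding_window_view(codes, width)
    onehot = np.zeros((win.shape[0], width, 4))
    for b in range(4):
        onehot[..., b] = win == b
    return onehot


def _seed_words(sequences, width: int, revcomp: bool, n_seeds: int,
                rng: np.random.Generator) -> list[str]:
    """Distinct high-count width-mers used as EM starting points."""
    counts: Counter[str] = Counter()
    for seq in sequences:
        for w in _kmers(seq.upper(), width):
            counts[w] += 1
            if revcomp:
                counts[reverse_complement(w)] += 1
    ranked = sorted(counts, key=lambda w: (-counts[w], w))
    seeds = ranked[:n_seeds]
    while len(seeds) < n_seeds:  # tiny inputs: top up with random words
        seeds.append("".join("ACGT"[i] for i in rng.integers(0, 4, width)))
    return seeds


def _seed_matrix(word: str, smooth_major: float = 0.7) -> np.ndarray:
    minor = (1.0 - smooth_major) / 3.0
    probs = np.full((len(word), 4), minor)
    codes = encode_sequence(word, allow_n=False)
    probs[np.arange(len(word)), codes] = smooth_major
    return probs


def discover_motif_oops(
    sequences,
    width: int,
    revcomp: bool = True,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-6,
    maxiter: int = 200,
    pseudocount: float = 0.25,
    name: str = "oops",
    ll_trace: list | None = None,
) -> PWM:
    """Single-motif discovery under the OOPS model.

    Each sequence is assumed to contain exactly one motif occurrence at
    an unknown offset (and, with ``revcomp``, on an unknown strand) with
    a uniform prior; everything else follows a 0-order background
    estimated from the input.  EM alternates offset/strand posteriors
    with letter-probability re-estimation (+``pseudocount`` per cell)
    until the log-likelihood improves by less than ``tol`` or ``maxiter``
    iterations elapse.  Restarts are seeded from distinct high-count
    width-mers (0.7/0.1 smoothing); the restart with the highest final
    log-likelihood wins.
    """
    sequences = [s.upper() for s in sequences]
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    min_len = min(len(s) for s in sequences)
    if width > min_len:
        raise ValueError(
            f"motif width {width} exceeds shortest sequence length {min_len}"
        )
    rng = np.random.default_rng(seed)

    coded = [encode_sequence(s, allow_n=False) for s in sequences]
    base_counts = np.bincount(np.concatenate(coded), minlength=4).astype(float)
    background = (base_counts + 1.0) / (base_counts.sum() + 4.0)
    log_bg = np.log(background)

    # per sequence: one-hot windows for both strands, background window scores
    onehots = []       # (n_win_i, W, 4); reverse strand reads revcomp windows
    onehots_rc = []
    for codes in coded:
        oh = _onehot_windows(codes, width)
        onehots.append(oh)
        if revcomp:
            # revcomp of window = reverse positions + complement channels
            onehots_rc.append(oh[:, ::-1, ::-1])
    n_strands = 2 if revcomp else 1

    def run_em(init_probs: np.ndarray) -> tuple[np.ndarray, float, list]:
        probs = init_probs.copy()
        prev_ll = -np.inf
        ll = prev_ll
        trace: list[float] = []
        for _ in range(maxiter):
            log_ratio = np.log(probs) - log_bg[None, :]
            counts = np.full((width, 4), pseudocount)
            ll = 0.0
            for i, oh in enumerate(onehots):
                scores = np.einsum("owb,wb->o", oh, log_ratio)
                if revcomp:
                    scores_rc = np.einsum("owb,wb->o", onehots_rc[i], log_ratio)
                    all_scores = np.concatenate([scores, scores_rc])
                else:
                    all_scores = scores
                m = all_scores.max()
                w = np.exp(all_scores - m)
                z = w.sum()
                post = w / z
                n_win = oh.shape[0]
                counts += np.einsum("o,owb->wb", post[:n_win], oh)
                if revcomp:
                    counts += np.einsum("o,owb->wb", post[n_win:], onehots_rc[i])
                # log P(seq) up to the constant background term over the
                # full sequence, which cancels in convergence checks but
                # is included for a proper likelihood value
                ll += (
                    m + np.log(z) - np.log(n_win * n_strands)
                    + float(log_bg[coded[i]].sum())
                )
            probs = counts / counts.sum(axis=1, keepdims=True)
            trace.append(ll)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        return probs, ll, trace

    best_probs, best_ll, best_trace = None, -np.inf, []
    for word in _seed_words(sequences, width, revcomp, restarts, rng):
        probs, ll, trace = run_em(_seed_matrix(word))
        if ll > best_ll:
            best_probs, best_ll, best_trace = probs, ll, trace
    if ll_trace is not None:
        ll_trace.extend(best_trace)
    return PWM(best_probs, name=name)


def build_pwm_ensemble(
    hits,
    group: str,
    n_sample: int = 50,
    replicates: int = 100,
    width: int = 10,
    base_seed: int = 0,
    with_replacement: bool = False,
    **em_kwargs,
) -> PWMEnsemble:
    """Ensemble of PWMs from repeated subsampling of one stratum.

    ``hits`` is the list of sequences belonging to the stratum (a
    quartile, or the whole pool for control ensembles).  Replicate r
    draws ``n_sample`` hits with seed ``base_seed + r`` and learns one
    OOPS motif; provenance (seed, sampled indices) is kept per PWM so
    any ensemble is reproducible from (base_seed, config) alone.
    """
    hits = list(hits)
    if len(hits) < n_sample and not with_replacement:
        raise ValueError(
            f"group '{group}' has {len(hits)} hits < n_sample={n_sample}; "
            "pass with_replacement=True to sample anyway"
        )
    ensemble = PWMEnsemble(group=group)
    for r in range(1, replicates + 1):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(hits), size=n_sample, replace=with_replacement)
        pwm = discover_motif_oops(
            [hits[i] for i in idx], width=width, seed=seed,
            name=f"{group}_rep{r}", **em_kwargs,
        )
        ensemble.pwms.append(pwm)
        ensemble.seeds.append(seed)
        ensemble.hit_indices.append(np.sort(idx))
    return ensemble
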