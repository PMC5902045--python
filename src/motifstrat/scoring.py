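"""PWM scoring of sequences: log-likelihoods, RLL, and site energies.

Conventions
-----------
Window log-likelihoods and the score bounds are in log2 units; site
mismatch energies are in natural-log units (they feed the logistic
occupancy model, which exponentiates base e).  The relative
log-likelihood (RLL)

    RLL = (x - Smin) / (Smax - Smin)

is invariant to the log base.  Before scanning, every sequence is padded
with "NN" on both ends so partial motif matches at the edges are scored;
an N contributes exactly 0 to a window's log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .motif import PWM, BASES

# N encodes as 4; rows of log-probability matrices get a zero column for it
_CODE = {b: i for i, b in enumerate(BASES + "N")}
_COMP_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

__all__ = [
    "ScoreResult",
    "encode_sequence",
    "reverse_complement",
    "window_loglik",
    "score_bounds",
    "rll_score",
    "score_sequences",
    "energy_score",
    "rank_correlation",
]


@dataclass
class ScoreResult:
    """Best-window score of one sequence under one PWM."""

    sequence_id: str
    x: float          # best window log-likelihood, log2
    s_min: float
    s_max: float
    rll: float
    offset: int       # 0-based start of the best window in NN-padded coordinates
    strand: str       # '+' or '-'


def encode_sequence(seq: str, allow_n: bool = True) -> np.ndarray:
    """Map ACGT(N) to integer codes 0..4; reject anything else."""
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None or (code == 4 and not allow_n):
            raise ValueError(f"invalid base {ch!r} at offset {i}")
        out[i] = code
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _log2_with_n(pwm: PWM) -> np.ndarray:
    """(W, 5) log2 probabilities with a zero column for N."""
    lp = np.zeros((pwm.width, 5))
    lp[:, :4] = np.log2(pwm.probs)
    return lp


def window_loglik(pwm: PWM, window: str) -> float:
    """log2-likelihood of one width-W window; N positions contribute 0."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != motif width {pwm.width}"
        )
    codes = encode_sequence(window)
    lp = _log2_with_n(pwm)
    return float(lp[np.arange(pwm.width), codes].sum())


def score_bounds(pwm: PWM) -> tuple[float, float]:
    """(Smin, Smax): extreme full-width, N-free window scores in log2."""
    lp = np.log2(pwm.probs)
    return float(lp.min(axis=1).sum()), float(lp.max(axis=1).sum())


def _window_scores(codes: np.ndarray, lp: np.ndarray) -> np.ndarray:
    """Scores of every width-W window of an encoded sequence (vectorised)."""
    W = lp.shape[0]
    n_win = codes.size - W + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    return lp[np.arange(W)[None, :], windows].sum(axis=1)


def rll_score(pwm: PWM, sequence: str, sequence_id: str = "") -> ScoreResult:
    """Best sliding-window score over both strands with NN edge padding.

    The sequence is padded with two Ns at each end; every width-W window
    of the padded sequence is scored forward and reverse-complemented,
    and the maximum is kept.  Ties resolve to the lowest offset and then
    to the forward strand.  RLL rescales the winning score between the
    motif's minimum and maximum possible (N-free) scores.
    """
    s_min, s_max = score_bounds(pwm)
    codes = encode_sequence(sequence)
    padded = np.concatenate([[4, 4], codes, [4, 4]]).astype(np.int8)
    W = pwm.width
    if padded.size < W:
        raise ValueError(
            f"sequence of length {codes.size} too short for motif width {W} "
            "even after NN padding"
        )
    lp = _log2_with_n(pwm)
    fwd = _window_scores(padded, lp)
    # reverse-strand score of window w == forward score of revcomp(w):
    # scan the reverse-complemented padded sequence and flip the offsets
    rc = _COMP_CODE[padded][::-1]
    rev = _window_scores(rc, lp)[::-1]

    n_win = fwd.size
    best = (-np.inf, 0, "+")
    for off in range(n_win):
        if fwd[off] > best[0]:
            best = (float(fwd[off]), off, "+")
        if rev[off] > best[0]:
            best = (float(rev[off]), off, "-")
    x = best[0]

    if s_max == s_min:
        warnings.warn(
            f"PWM '{pwm.name}' has equal minimum and maximum scores; "
            "RLL defined as 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        rll = 1.0
    else:
        # N-padded edge windows can score above the N-free maximum (an N
        # contributes 0, every concrete log-probability is <= 0), so the
        # ratio is clipped back into [0, 1]
        rll = min(1.0, max(0.0, (x - s_min) / (s_max - s_min)))
    return ScoreResult(sequence_id, x, s_min, s_max, rll, best[1], best[2])


def score_sequences(pwm: PWM, sequences, ids=None) -> list[ScoreResult]:
    """rll_score over a collection; ids default to seq0, seq1, ..."""
    results = []
    for i, seq in enumerate(sequences):
        sid = ids[i] if ids is not None else f"seq{i}"
        try:
            results.append(rll_score(pwm, seq, sequence_id=sid))
        except ValueError as exc:
            raise ValueError(f"scoring failed for sequence {sid!r}: {exc}") from exc
    return results


def energy_score(pwm: PWM, site: str) -> float:
    """Consensus-referenced mismatch energy of an exact-width, N-free site.

    E = sum_i ln( max_b p_ib / p_i,site_i ) >= 0, natural log, with
    E = 0 exactly when the site is a motif consensus.
    """
    if len(site) != pwm.width:
        raise ValueError(f"site length {len(site)} != motif width {pwm.width}")
    codes = encode_sequence(site, allow_n=False)
    lnp = np.log(pwm.probs)
    return float((lnp.max(axis=1) - lnp[np.arange(pwm.width), codes]).sum())


def site_energies(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Vectorised energy_score over an (n, W) integer-coded site matrix."""
    lnp = np.log(pwm.probs)
    per_pos = lnp.max(axis=1)[None, :] - lnp[np.arange(pwm.width)[None, :], encoded]
    return per_pos.sum(axis=1)


def best_window_energy(pwm: PWM, codes: np.ndarray) -> float:
    """Lowest mismatch energy over all full-width windows, both strands."""
    W = pwm.width
    if codes.size < W:
        raise ValueError("sequence shorter than motif width")
    lnp = np.log(pwm.probs)
    lnp5 = np.zeros((W, 5))
    lnp5[:, :4] = lnp.max(axis=1)[:, None] - lnp  # per-position energies
    fwd = _window_scores(codes, lnp5)
    rev = _window_scores(_COMP_CODE[codes][::-1], lnp5)
    return float(min(fwd.min(), rev.min()))


def rank_correlation(predicted, observed) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) and linear-fit r-squared."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size or predicted.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(predicted, observed).statistic
    r2 = stats.pearsonr(predicted, observed).statistic ** 2
    return float(rho), float(r2)
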