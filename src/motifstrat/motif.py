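"""Position count/weight matrices and elementary motif manipulations.

Matrices are numpy arrays of shape (W, 4) with the base order fixed as
A, C, G, T throughout the package.  A :class:`PCM` holds non-negative
integer counts per position; a :class:`PWM` holds strictly positive
per-position base probabilities (rows sum to 1) plus a background
composition used by downstream scoring.

Information content is computed against a uniform background:
``IC_i = 2 + sum_b p_ib * log2(p_ib)`` bits, in [0, 2] per position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# A<->T, C<->G under the fixed A,C,G,T column order
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])

__all__ = [
    "BASES",
    "PCM",
    "PWM",
    "pcm_to_pwm",
    "information_content",
    "trim_flanks",
    "reverse_complement_pwm",
    "consensus_sequence",
]


@dataclass
class PCM:
    """Position count matrix: integer base counts per motif position."""

    counts: np.ndarray
    name: str = "pcm"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"PCM must have shape (W, 4), got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("PCM counts must be non-negative")
        if not np.any(self.counts.sum(axis=1) > 0):
            raise ValueError("PCM must have at least one position with observations")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def column_sums(self) -> np.ndarray:
        """Number of observed nucleotides n_i per position."""
        return self.counts.sum(axis=1)


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    Parameters
    ----------
    probs : (W, 4) array
        Row-stochastic, strictly positive (pseudocounted upstream).
    name : str
        Identifier carried through IO and provenance tables.
    background : length-4 array
        Base composition assumed by scoring; defaults to uniform.
    """

    probs: np.ndarray
    name: str = "pwm"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM must have shape (W, 4), got {self.probs.shape}")
        if np.any(self.probs <= 0):
            raise ValueError("PWM entries must be strictly positive")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ValueError("PWM rows must sum to 1")
        # store exactly row-stochastic for numerical hygiene
        self.probs = self.probs / rowsums[:, None]

    @property
    def width(self) -> int:
        return self.probs.shape[0]


def pcm_to_pwm(pcm: PCM, pseudocount_mode: str = "background-split") -> PWM:
    """Convert counts to probabilities with a total pseudocount of n_i.

    The per-position pseudocount mass equals n_i, the number of observed
    nucleotides at that position.  Two arithmetics are supported:

    - ``"background-split"`` (default): the n_i pseudocounts are
      apportioned by the (uniform) background, so
      ``p_ib = (c_ib + 0.25 * n_i) / (2 * n_i)``.
    - ``"per-base"``: every base receives n_i pseudocounts,
      ``p_ib = (c_ib + n_i) / (5 * n_i)``.
    """
    n = pcm.column_sums().astype(float)
    zero = np.nonzero(n == 0)[0]
    if zero.size:
        raise ValueError(
            f"PCM '{pcm.name}' has zero observations at position {int(zero[0])}"
        )
    c = pcm.counts.astype(float)
    if pseudocount_mode == "background-split":
        probs = (c + 0.25 * n[:, None]) / (2.0 * n[:, None])
    elif pseudocount_mode == "per-base":
        probs = (c + n[:, None]) / (5.0 * n[:, None])
    else:
        raise ValueError(f"unknown pseudocount_mode: {pseudocount_mode!r}")
    return PWM(probs, name=pcm.name)


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Per-position and total information content in bits.

    Uses a uniform background: IC_i = 2 + sum_b p_ib log2 p_ib.
    """
    per_pos = 2.0 + np.sum(pwm.probs * np.log2(pwm.probs), axis=1)
    per_pos = np.clip(per_pos, 0.0, 2.0)
    return per_pos, float(per_pos.sum())


def trim_flanks(
    pwm: PWM,
    target_width: int | None = None,
    ic_threshold: float | None = None,
) -> PWM:
    """Remove low-information columns from the motif ends only.

    Exactly one of ``target_width`` / ``ic_threshold`` must be given.
    Width mode repeatedly drops whichever terminal column has lower IC
    (ties drop from the right) until the requested width is reached.
    Threshold mode drops terminal columns whose IC falls below the
    threshold, stopping at the first informative column on each side.
    """
    if (target_width is None) == (ic_threshold is None):
        raise ValueError("give exactly one of target_width or ic_threshold")
    ic, _ = information_content(pwm)
    lo, hi = 0, pwm.width  # surviving half-open block [lo, hi)

    if target_width is not None:
        if target_width > pwm.width:
            raise ValueError(
                f"target_width {target_width} exceeds motif width {pwm.width}"
            )
        if target_width < 1:
            raise ValueError("target_width must be >= 1 (cannot trim all columns)")
        while hi - lo > target_width:
            if ic[lo] < ic[hi - 1]:
                lo += 1
            else:  # tie -> drop from the right
                hi -= 1
    else:
        if not (0.0 <= ic_threshold <= 2.0):
            raise ValueError("ic_threshold must be in [0, 2] bits")
        while lo < hi and ic[lo] < ic_threshold:
            lo += 1
        while hi > lo and ic[hi - 1] < ic_threshold:
            hi -= 1
        if lo == hi:
            raise ValueError("trimming at this threshold would remove every column")

    trimmed = PWM(pwm.probs[lo:hi].copy(), name=pwm.name, background=pwm.background)
    return trimmed


def reverse_complement_pwm(pwm: PWM) -> PWM:
    """Motif on the opposite strand: reverse positions, complement bases."""
    probs = pwm.probs[::-1, _COMPLEMENT_PERM].copy()
    return PWM(probs, name=pwm.name, background=pwm.background[_COMPLEMENT_PERM])


def consensus_sequence(pwm: PWM) -> str:
    """Per-position argmax base; ties resolve to the alphabetically first."""
    # np.argmax already returns the first (lowest-index = alphabetically
    # first in ACGT order) maximal entry
    return "".join(BASES[i] for i in np.argmax(pwm.probs, axis=1))
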