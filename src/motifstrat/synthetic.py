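"""Synthetic study generators with known ground truth.

Every generator is a pure function of a :class:`SyntheticSpec` plus its
own arguments, so identical seeds give byte-identical artifacts.  One
biophysical mechanism — the logistic occupancy of a site with mismatch
energy E, ``1 / (1 + exp(E - mu))`` — is shared across all of them:

- the B1H pool generator accepts random sequences with probability equal
  to the occupancy of their best window (selection stringency = mu_sel;
  larger mu_sel is more permissive and admits more low-affinity hits);
- PBM fluorescence is total occupancy over all probe windows on both
  strands, scaled and jittered with multiplicative log-normal noise;
- ChIP fold enrichment is occupancy of the planted site, same noise;
- the EMSA titration generator inverts the occupancy model directly
  with additive truncated-normal noise on proportions bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .motif import PWM, BASES, information_content
from .scoring import _COMP_CODE
from .evaluate import PBMProbe, ChIPPeak

__all__ = [
    "SyntheticSpec",
    "random_ground_truth_pwm",
    "simulate_b1h_pool",
    "simulate_pbm",
    "simulate_genome_peaks",
    "simulate_emsa",
]


@dataclass
class SyntheticSpec:
    """Ground truth and nuisance parameters of one synthetic study."""

    ground_truth: PWM
    seed: int = 0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    mu_sel: float = 6.0          # selection/occupancy chemical potential
    pbm_alpha: float = 1000.0    # fluorescence scale
    pbm_sigma: float = 0.2       # log-normal noise sd on fluorescence
    chip_beta: float = 10.0      # fold-enrichment scale
    chip_sigma: float = 0.2      # log-normal noise sd on enrichment


def random_ground_truth_pwm(
    width: int, target_total_ic: float, seed: int = 0
) -> PWM:
    """Dirichlet-column PWM whose total IC is tuned to a target.

    A single (width, 4) block of uniform variates is drawn once from the
    seed; columns are gamma quantiles of those variates at concentration
    alpha, normalised to probabilities.  Total IC is monotone in alpha,
    so alpha is found by bisection until the realised IC is within 5% of
    the target.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if not (0.0 < target_total_ic < 2.0 * width):
        raise ValueError("target IC must lie in (0, 2*width) bits")
    rng = np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1 - 1e-12, size=(width, 4))

    def pwm_at(alpha: float) -> PWM:
        g = gamma_dist.ppf(u, a=alpha)
        g = np.maximum(g, 1e-300)
        return PWM(g / g.sum(axis=1, keepdims=True), name="ground_truth")

    def ic_at(alpha: float) -> float:
        return information_content(pwm_at(alpha))[1]

    lo, hi = 1e-3, 1e3  # IC decreasing in alpha: lo -> sharp, hi -> uniform
    if not (ic_at(hi) <= target_total_ic <= ic_at(lo)):
        raise ValueError(
            f"target IC {target_total_ic} bits unreachable for width {width}"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if ic_at(mid) > target_total_ic:
            lo = mid
        else:
            hi = mid
        if abs(ic_at(mid) - target_total_ic) <= 0.05 * target_total_ic:
            return pwm_at(mid)
    raise ValueError("bisection failed to reach the target IC")


def _decode(codes: np.ndarray) -> list[str]:
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[codes]]


def _batch_best_energies(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Best-window (lowest) mismatch energy per row of a (B, L) code array."""
    W = pwm.width
    lnp = np.log(pwm.probs)
    pe = lnp.max(axis=1)[:, None] - lnp          # (W, 4) per-position energies
    pe5 = np.concatenate([pe, np.zeros((W, 1))], axis=1)

    def strand_min(c: np.ndarray) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(c, W, axis=1)
        e = pe5[np.arange(W)[None, None, :], win].sum(axis=2)
        return e.min(axis=1)

    fwd = strand_min(codes)
    rev = strand_min(_COMP_CODE[codes][:, ::-1])
    return np.minimum(fwd, rev)


def _batch_total_occupancy(pwm: PWM, codes: np.ndarray, mu: float) -> np.ndarray:
    """Sum of logistic window occupancies over both strands, per row."""
    W = pwm.width
    lnp = np.log(pwm.probs)
    pe = lnp.max(axis=1)[:, None] - lnp
    pe5 = np.concatenate([pe, np.zeros((W, 1))], axis=1)

    def strand_occ(c: np.ndarray) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(c, W, axis=1)
        e = pe5[np.arange(W)[None, None, :], win].sum(axis=2)
        return (1.0 / (1.0 + np.exp(e - mu))).sum(axis=1)

    return strand_occ(codes) + strand_occ(_COMP_CODE[codes][:, ::-1])


def simulate_b1h_pool(
    spec: SyntheticSpec,
    n_hits: int = 2000,
    hit_length: int = 25,
    mu_sel: float | None = None,
) -> list[str]:
    """Affinity-selected pool of fixed-length hits.

    Background sequences are drawn and accepted with probability
    ``1 / (1 + exp(E_best - mu_sel))`` where E_best is the lowest
    mismatch energy over all windows on both strands.  Stringent
    selection (small mu_sel) enriches near-consensus hits; permissive
    selection admits low-affinity and background sequences.
    """
    mu = spec.mu_sel if mu_sel is None else mu_sel
    W = spec.ground_truth.width
    if hit_length < W:
        raise ValueError("hit_length must be >= motif width")
    rng = np.random.default_rng(spec.seed)
    accepted: list[str] = []
    total_drawn = 0
    batch = max(2 * n_hits, 1000)
    while len(accepted) < n_hits:
        codes = rng.choice(4, size=(batch, hit_length), p=spec.background)
        e_best = _batch_best_energies(spec.ground_truth, codes)
        p_accept = 1.0 / (1.0 + np.exp(e_best - mu))
        keep = rng.random(batch) < p_accept
        accepted.extend(_decode(codes[keep]))
        total_drawn += batch
        if total_drawn > 1e6 and len(accepted) / total_drawn < 1e-6:
            raise RuntimeError(
                "acceptance rate below 1e-6; increase mu_sel (selection "
                "too stringent for this ground truth)"
            )
    return accepted[:n_hits]


def simulate_pbm(
    spec: SyntheticSpec,
    n_probes: int = 4000,
    probe_length: int = 36,
    alpha: float | None = None,
    sigma: float | None = None,
) -> pd.DataFrame:
    """PBM-style probe table: fluorescence ~ total occupancy x noise.

    Fluorescence = alpha * (sum over both strands' windows of logistic
    occupancy at mu_sel) * exp(eps), eps ~ Normal(0, sigma^2).
    Returns columns probe_id / sequence / fluorescence.
    """
    if n_probes < 200:
        raise ValueError("need n_probes >= 200")
    a = spec.pbm_alpha if alpha is None else alpha
    s = spec.pbm_sigma if sigma is None else sigma
    rng = np.random.default_rng(spec.seed + 1)
    codes = rng.choice(4, size=(n_probes, probe_length), p=spec.background)
    occ = _batch_total_occupancy(spec.ground_truth, codes, spec.mu_sel)
    noise = np.exp(rng.normal(0.0, s, size=n_probes)) if s > 0 else 1.0
    fluor = a * occ * noise
    return pd.DataFrame({
        "probe_id": [f"probe{i:05d}" for i in range(n_probes)],
        "sequence": _decode(codes),
        "fluorescence": fluor,
    })


def _site_with_energy(
    pwm: PWM, target_e: float, rng: np.random.Generator, tol: float = 0.5,
    max_steps: int = 200,
) -> np.ndarray:
    """Random walk from the consensus toward a target mismatch energy."""
    lnp = np.log(pwm.probs)
    pe = lnp.max(axis=1)[:, None] - lnp
    site = pe.argmin(axis=1).copy()  # a consensus

    def energy(s):
        return float(pe[np.arange(pwm.width), s].sum())

    for _ in range(max_steps):
        e = energy(site)
        if abs(e - target_e) <= tol:
            break
        pos = int(rng.integers(pwm.width))
        base = int(rng.integers(4))
        trial = site.copy()
        trial[pos] = base
        if abs(energy(trial) - target_e) < abs(e - target_e):
            site = trial
    return site


def simulate_genome_peaks(
    spec: SyntheticSpec,
    genome_length: int = 200_000,
    n_sites: int = 100,
    site_energy_range: tuple[float, float] = (0.0, 8.0),
    mask_fraction: float = 0.05,
    chrom: str = "chrSyn",
    max_tries: int = 10_000,
):
    """Synthetic genome with planted sites, 100-bp peaks, and a repeat mask.

    Returns (genome dict, list of ChIPPeak with noisy fold enrichment,
    mask interval list, planted-site DataFrame with true energies).
    """
    rng = np.random.default_rng(spec.seed + 2)
    W = spec.ground_truth.width
    codes = rng.choice(4, size=genome_length, p=spec.background)

    # non-overlapping mask intervals of 500 bp covering ~mask_fraction
    mask: list[tuple[str, int, int]] = []
    target_masked = int(mask_fraction * genome_length)
    masked = 0
    occupied = np.zeros(genome_length, dtype=bool)
    tries = 0
    while masked < target_masked:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place mask intervals")
        s = int(rng.integers(0, genome_length - 500))
        if occupied[s:s + 500].any():
            continue
        occupied[s:s + 500] = True
        mask.append((chrom, s, s + 500))
        masked += 500

    peaks, rows = [], []
    for i in range(n_sites):
        target_e = float(rng.uniform(*site_energy_range))
        site = _site_with_energy(spec.ground_truth, target_e, rng)
        placed = False
        for _ in range(max_tries):
            s = int(rng.integers(50, genome_length - 50 - W))
            c = s + W // 2
            if occupied[c - 50:c + 50].any():
                continue
            codes[s:s + W] = site
            occupied[c - 50:c + 50] = True
            lnp = np.log(spec.ground_truth.probs)
            pe = lnp.max(axis=1)[:, None] - lnp
            e_true = float(pe[np.arange(W), site].sum())
            occ = 1.0 / (1.0 + np.exp(e_true - spec.mu_sel))
            fe = spec.chip_beta * occ * float(
                np.exp(rng.normal(0.0, spec.chip_sigma))
            )
            peaks.append(ChIPPeak(chrom, c - 50, c + 50, fe, name=f"peak{i}"))
            rows.append({"name": f"peak{i}", "site_start": s,
                         "energy": e_true, "occupancy": occ})
            placed = True
            break
        if not placed:
            raise RuntimeError("placement collision limit reached")
    genome = {chrom: "".join(np.array(list(BASES))[codes])}
    return genome, peaks, mask, pd.DataFrame(rows)


def simulate_emsa(
    spec: SyntheticSpec,
    site_energies,
    mu_star: float,
    M_star: float,
    sigma: float = 0.0,
) -> pd.DataFrame:
    """Titration table from the occupancy model with known parameters.

    observed = clamp(M*/(1+exp(E-mu*)) + Normal(0, sigma^2), 0, 1).
    """
    if not (0.0 < M_star <= 1.0):
        raise ValueError("M_star must be in (0, 1]")
    E = np.asarray(site_energies, dtype=float)
    rng = np.random.default_rng(spec.seed + 3)
    obs = M_star / (1.0 + np.exp(E - mu_star))
    if sigma > 0:
        obs = obs + rng.normal(0.0, sigma, size=E.size)
    obs = np.clip(obs, 0.0, 1.0)
    return pd.DataFrame({
        "site_id": [f"site{i}" for i in range(E.size)],
        "E": E,
        "proportion_bound": obs,
    })
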