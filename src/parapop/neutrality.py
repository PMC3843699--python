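"""Site-frequency-spectrum and haplotype-based neutrality statistics.

All statistics are on the per-gene (total, not per-site) scale, matching
the magnitudes DnaSP/DH-style tools print:

* Tajima's D contrasts theta_pi with Watterson's S/a1.
* Fu's Fs is ln(S'/(1-S')) where S' = P(K >= k_obs | theta_pi) under the
  Ewens sampling formula, computed with unsigned Stirling numbers of the
  first kind in log space.
* Fay & Wu's H = theta_pi - theta_H weights high-frequency derived
  variants; theta_L is Zeng's linear estimator and H = 2(theta_pi-theta_L).
* The normalized H (nH) divides theta_pi - theta_L by Zeng et al.'s
  variance estimate using theta_W and theta^2 = S(S-1)/(a1^2 + a2).
* The Ewens-Watterson test scores observed haplotype homozygosity F
  against Monte-Carlo samples from the Ewens distribution conditional on
  the observed number of distinct haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .popdata import SiteTable


@dataclass
class SFS:
    """Unfolded site frequency spectrum: xi[i-1] sites at derived count i."""

    n: int
    xi: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.shape != (self.n - 1,):
            raise ValueError(f"xi must have length n-1={self.n - 1}")
        if (self.xi < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def S(self) -> float:
        return float(self.xi.sum())

    def theta_pi(self) -> float:
        i = np.arange(1, self.n)
        return float((self.xi * 2.0 * i * (self.n - i)).sum() / (self.n * (self.n - 1)))

    def theta_H(self) -> float:
        i = np.arange(1, self.n)
        return float((self.xi * 2.0 * i * i).sum() / (self.n * (self.n - 1)))

    def theta_L(self) -> float:
        i = np.arange(1, self.n)
        return float((self.xi * i).sum() / (self.n - 1))


def sfs_from_sites(sites: SiteTable, n: Optional[int] = None) -> SFS:
    """Build the unfolded SFS from polarized site rows (unpolarizable excluded)."""
    n = n or sites.n
    xi = np.zeros(n - 1)
    for r in sites:
        if r.polarizable is False or r.derived_count is None:
            continue
        if not (1 <= r.derived_count <= n - 1):
            raise ValueError(f"derived_count {r.derived_count} out of [1, n-1]")
        xi[r.derived_count - 1] += 1
    return SFS(n, xi)


# ---------------------------------------------------------------------------
# Tajima's D

def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i ** power for i in range(1, n))


def tajimas_d(S: float, theta_pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites and total pairwise diversity."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        return float("nan")
    a1 = _harmonic(n, 1)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi_total - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fu's Fs

@lru_cache(maxsize=32)
def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, j)| for j=0..n (exact integer recurrence, then log)."""
    row = [1]  # |s(0,0)|
    for m in range(n):
        new = [0] * (m + 2)
        for j in range(m + 2):
            prev_same = row[j] if j < len(row) else 0
            prev_shift = row[j - 1] if 1 <= j <= len(row) else 0
            new[j] = m * prev_same + prev_shift
        row = new
    out = np.full(n + 1, -np.inf)
    for j, v in enumerate(row):
        if v > 0:
            out[j] = math.log(v)
    return out


def ewens_k_distribution_log(n: int, theta: float) -> np.ndarray:
    """log P(K=j | theta, n), j=0..n, from the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_first(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    j = np.arange(n + 1)
    return logs + j * math.log(theta) - log_rising


def fus_fs(n: int, k: int, theta_pi_total: float) -> float:
    """Fu's Fs from sample size, distinct-haplotype count and theta_pi."""
    if not (1 <= k <= n):
        raise ValueError("k must lie in [1, n]")
    if theta_pi_total <= 0:
        return float("nan")
    if k == 1:
        return float("inf")  # P(K >= 1) = 1 exactly
    logp = ewens_k_distribution_log(n, theta_pi_total)
    # S' = P(K >= k)
    tail = logp[k:]
    m = tail.max()
    log_sp = m + math.log(np.exp(tail - m).sum())
    log_sp = min(log_sp, 0.0)
    sp = math.exp(log_sp)
    if sp >= 1.0:
        return float("-inf")
    if sp <= 0.0:
        return float("inf")
    return math.log(sp / (1.0 - sp))


# ---------------------------------------------------------------------------
# Fay & Wu's H and Zeng's normalized H

def fay_wu_h(sfs: SFS) -> Tuple[float, float, float]:
    """(H, theta_H, theta_L); H = theta_pi - theta_H on the per-gene scale."""
    if sfs.S == 0:
        return float("nan"), 0.0, 0.0
    th = sfs.theta_H()
    tl = sfs.theta_L()
    return sfs.theta_pi() - th, th, tl


def zeng_nh(sfs: SFS) -> float:
    """Zeng et al.'s normalized H: (theta_pi - theta_L) / sqrt(Var)."""
    n = sfs.n
    S = sfs.S
    if S < 1:
        return float("nan")
    a1 = _harmonic(n, 1)
    a2 = _harmonic(n, 2)
    bn1 = _harmonic(n + 1, 2)  # sum_{i=1}^{n} 1/i^2
    theta_w = S / a1
    theta2 = S * (S - 1) / (a1 ** 2 + a2)
    var = (theta_w * (n - 2) / (6.0 * (n - 1))
           + theta2 * (18.0 * n * n * (3.0 * n + 2.0) * bn1
                       - (88.0 * n ** 3 + 9.0 * n ** 2 - 13.0 * n + 6.0))
           / (9.0 * n * (n - 1) ** 2))
    if var <= 0:
        return float("nan")
    return (sfs.theta_pi() - sfs.theta_L()) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Ewens-Watterson test

def ewens_expected_k(theta: float, n: int) -> float:
    return sum(theta / (theta + i) for i in range(n))


def solve_theta_for_k(k: int, n: int) -> float:
    """theta with E[K | theta, n] = k (bisection; K in (1, n))."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9
    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if ewens_expected_k(mid, n) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _crp_sample(n: int, theta: float, rng: np.random.Generator) -> List[int]:
    """One Ewens partition of n via the Chinese-restaurant construction."""
    counts: List[int] = []
    total = 0
    for i in range(n):
        u = rng.random() * (theta + i)
        if u < theta or not counts:
            counts.append(1)
        else:
            # pick an existing class proportional to its size
            r = u - theta
            acc = 0.0
            for j, c in enumerate(counts):
                acc += c
                if r < acc:
                    counts[j] += 1
                    break
            else:
                counts[-1] += 1
        total += 1
    return counts


def ewens_watterson_test(hap_counts: Sequence[int], reps: int = 1000,
                         rng_seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None
                         ) -> Tuple[float, float, float]:
    """(F_obs, p_lower, p_upper): homozygosity against the Ewens null.

    Null samples are Ewens partitions conditional on (n, k): theta is tuned
    so E[K] = k and Chinese-restaurant draws are rejection-filtered to K=k.
    ``p_lower`` is P(F_null <= F_obs), the tail sensitive to overly even
    haplotype frequencies.
    """
    counts = [int(c) for c in hap_counts]
    n = sum(counts)
    k = len(counts)
    if n < 2:
        raise ValueError("need n >= 2")
    F_obs = sum((c / n) ** 2 for c in counts)
    if k == 1 or k == n:
        # single possible configuration
        return F_obs, 1.0, 1.0
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    theta = solve_theta_for_k(k, n)
    sims = []
    attempts = 0
    max_attempts = reps * 200
    while len(sims) < reps and attempts < max_attempts:
        attempts += 1
        part = _crp_sample(n, theta, rng)
        if len(part) == k:
            sims.append(sum((c / n) ** 2 for c in part))
    if not sims:
        raise RuntimeError("conditional Ewens sampling failed to accept any draws")
    m = len(sims)
    eps = 1e-12
    lower = (1 + sum(1 for f in sims if f <= F_obs + eps)) / (m + 1)
    upper = (1 + sum(1 for f in sims if f >= F_obs - eps)) / (m + 1)
    return F_obs, lower, upper


# ---------------------------------------------------------------------------
# Bundled per-region statistics

@dataclass
class NeutralityStats:
    S: float
    k: int
    D: float
    Fs: float
    H: float
    nH: float
    EW_F: float
    EW_p_lower: float
    theta_pi_total: float
    theta_w_total: float
    theta_H: float
    theta_L: float
    polarizable_S: float


def neutrality_stats(sites: SiteTable, hap_counts: Sequence[int],
                     ew_reps: int = 1000,
                     rng: Optional[np.random.Generator] = None) -> NeutralityStats:
    """All neutrality statistics for one region from its polarized SiteTable."""
    n = sites.n
    tpt = 0.0
    from .diversity import theta_pi_total_from_sites, watterson_a1
    tpt = theta_pi_total_from_sites(sites)
    sfs = sfs_from_sites(sites)
    H, tH, tL = fay_wu_h(sfs)
    D = tajimas_d(sites.S, tpt, n) if sites.S >= 1 else float("nan")
    Fs = fus_fs(n, len(hap_counts), tpt)
    nH = zeng_nh(sfs)
    F, p_low, _ = ewens_watterson_test(hap_counts, reps=ew_reps, rng=rng)
    return NeutralityStats(
        S=sites.S, k=len(hap_counts), D=D, Fs=Fs, H=H, nH=nH,
        EW_F=F, EW_p_lower=p_low,
        theta_pi_total=tpt, theta_w_total=sites.S / watterson_a1(n),
        theta_H=tH, theta_L=tL, polarizable_S=sfs.S)
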