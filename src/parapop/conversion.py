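"""MaxChi-style breakpoint detection to nominate gene-conversion tracts.

For an aligned sequence pair, each comparable (gap-free) position is a
match or mismatch. A window of 2k such positions slides along the
sequence; at its midpoint a 2x2 table (left/right half x match/mismatch)
is scored with Pearson's chi-square. A sharp change in mismatch density —
the signature of a conversion/recombination breakpoint — maximizes the
statistic. Significance is assessed by permuting the match/mismatch
sequence, which preserves the overall divergence but destroys spatial
structure, with a Bonferroni correction across reported candidates.

The analysis pipeline does not depend on detection: externally supplied
tracts (``coalsim.DEFAULT_TRACTS``) can always be passed straight to the
masking step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .popdata import SiteTable

_BASES = set("ACGT")


@dataclass
class ConversionCandidate:
    pair: Tuple[str, str]
    breakpoint_pos: int          # frame position of the window midpoint
    window: Tuple[int, int]      # frame positions of window ends
    chi2: float
    perm_p: float                # Bonferroni-adjusted permutation p
    implicated_positions: List[int]  # mismatch positions in the enriched half

    @property
    def tract(self) -> Tuple[int, int]:
        if not self.implicated_positions:
            return (self.breakpoint_pos, self.breakpoint_pos)
        return (min(self.implicated_positions), max(self.implicated_positions))


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of [[a, b], [c, d]] without continuity correction."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if not all((r1, r2, c1, c2)):
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def _max_chi2(mismatch: np.ndarray, k: int) -> Tuple[float, int]:
    """Maximum split chi-square over all 2k-windows; returns (chi2, center
    index into the site sequence)."""
    best = -1.0
    best_center = k
    csum = np.concatenate([[0], np.cumsum(mismatch)])
    for start in range(0, len(mismatch) - 2 * k + 1):
        mid = start + k
        left_mm = int(csum[mid] - csum[start])
        right_mm = int(csum[start + 2 * k] - csum[mid])
        chi2 = _chi2_2x2(left_mm, k - left_mm, right_mm, k - right_mm)
        if chi2 > best:
            best = chi2
            best_center = mid
    return best, best_center


def maxchi_scan(seqA: str, seqB: str, window_sites: int = 20,
                permutations: int = 200,
                rng: Optional[np.random.Generator] = None,
                alpha: float = 0.05,
                pair_labels: Tuple[str, str] = ("A", "B")
                ) -> List[ConversionCandidate]:
    """Scan an aligned pair for a mismatch-density breakpoint.

    Returns candidates sorted by chi-square; ``perm_p`` is already
    Bonferroni-multiplied. An empty list means no usable signal (identical
    sequences or too few comparable positions).
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be aligned to equal length")
    if rng is None:
        rng = np.random.default_rng()
    k = int(window_sites)
    positions = [i + 1 for i, (a, b) in enumerate(zip(seqA.upper(), seqB.upper()))
                 if a in _BASES and b in _BASES]
    if len(positions) < 2 * k:
        return []
    mismatch = np.array([seqA[p - 1] != seqB[p - 1] for p in positions], dtype=int)
    if mismatch.sum() == 0 or mismatch.sum() == len(mismatch):
        return []
    obs_chi2, center = _max_chi2(mismatch, k)
    # permutation null of the maximum statistic
    geq = 0
    perm = mismatch.copy()
    for _ in range(permutations):
        rng.shuffle(perm)
        null_chi2, _ = _max_chi2(perm, k)
        if null_chi2 >= obs_chi2:
            geq += 1
    p = (1 + geq) / (permutations + 1)
    n_candidates = 1  # one maximum reported per pair
    p_adj = min(1.0, p * n_candidates)
    lo, hi = center - k, center + k
    left = mismatch[lo:center].sum()
    right = mismatch[center:hi].sum()
    dense = range(lo, center) if left > right else range(center, hi)
    implicated = [positions[i] for i in dense if mismatch[i]]
    cand = ConversionCandidate(
        pair=pair_labels,
        breakpoint_pos=positions[center],
        window=(positions[lo], positions[hi - 1]),
        chi2=float(obs_chi2),
        perm_p=float(p_adj),
        implicated_positions=implicated,
    )
    return [cand] if p_adj <= alpha else []


def nominate_tracts(candidates: Sequence[ConversionCandidate],
                    sites: Optional[SiteTable] = None) -> List[Tuple[int, int]]:
    """Minimum conversion tracts: the closed span of the implicated sites.

    When a SiteTable is given, each tract is snapped to the span of the
    segregating sites it contains (the paper-style minimum tract).
    """
    tracts = []
    for cand in candidates:
        a, b = cand.tract
        if sites is not None:
            inside = [p for p in sites.positions if a <= p <= b]
            if inside:
                a, b = min(inside), max(inside)
        tracts.append((a, b))
    return sorted(set(tracts))


def read_tracts_tsv(path) -> List[Tuple[int, int]]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["start", "end", "label"])
    return [(int(r.start), int(r.end)) for r in df.itertuples()]


def write_tracts_tsv(tracts: Sequence[Tuple[int, int]], path,
                     labels: Optional[Sequence[str]] = None) -> None:
    import pandas as pd
    labels = labels or [f"tract{i+1}" for i in range(len(tracts))]
    pd.DataFrame([(a, b, l) for (a, b), l in zip(tracts, labels)]).to_csv(
        path, sep="\t", header=False, index=False)
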