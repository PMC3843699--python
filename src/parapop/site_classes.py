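"""Classification of sites by their coexistence across a paralogue pair.

A position is FIXED when the two paralogues are each monomorphic but for
different bases (the hallmark of suppressed non-allelic gene conversion),
SHARED when both are polymorphic, SPECIFIC_A / SPECIFIC_B when only one is,
and INVARIANT otherwise. Classes partition the frame; counting them per
region and contrasting regions with Pearson chi-square is the core
concerted-evolution diagnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .popdata import RegionMap, SiteTable

FIXED = "FIXED"
SHARED = "SHARED"
SPECIFIC_A = "SPECIFIC_A"
SPECIFIC_B = "SPECIFIC_B"
INVARIANT = "INVARIANT"
CLASSES = (FIXED, SHARED, SPECIFIC_A, SPECIFIC_B)


@dataclass
class SiteClassification:
    """Non-invariant positions mapped to their class; INVARIANT is implicit."""

    classes: Dict[int, str]
    L: int

    def counts(self) -> Counter:
        return Counter(self.classes.values())

    def positions_of(self, cls: str) -> List[int]:
        return sorted(p for p, c in self.classes.items() if c == cls)

    def swapped(self) -> "SiteClassification":
        swap = {SPECIFIC_A: SPECIFIC_B, SPECIFIC_B: SPECIFIC_A}
        return SiteClassification(
            {p: swap.get(c, c) for p, c in self.classes.items()}, self.L)


def _is_polymorphic(record, n: int, maf_threshold: float) -> bool:
    return record is not None and record.minor_count / n >= maf_threshold


def classify_paralogue_sites(sites_a: SiteTable, consensus_a: str,
                             sites_b: SiteTable, consensus_b: str,
                             maf_threshold: float = 0.0) -> SiteClassification:
    """Classify every frame position for a paralogue pair on a common frame.

    The pseudogene-side data may be frequency-only, which is why the inputs
    are site tables plus consensus sequences rather than full alignments.
    Sites below ``maf_threshold`` are treated as monomorphic beforehand.
    """
    if len(consensus_a) != len(consensus_b):
        raise ValueError("paralogue consensuses are on different frames "
                         f"({len(consensus_a)} vs {len(consensus_b)})")
    L = len(consensus_a)
    rec_a = {r.position: r for r in sites_a}
    rec_b = {r.position: r for r in sites_b}
    classes: Dict[int, str] = {}
    for pos in sorted(set(rec_a) | set(rec_b) | {
            p + 1 for p in range(L) if consensus_a[p] != consensus_b[p]}):
        if pos < 1 or pos > L:
            raise ValueError(f"site position {pos} outside frame [1, {L}]")
        poly_a = _is_polymorphic(rec_a.get(pos), sites_a.n, maf_threshold)
        poly_b = _is_polymorphic(rec_b.get(pos), sites_b.n, maf_threshold)
        if poly_a and poly_b:
            classes[pos] = SHARED
        elif poly_a:
            classes[pos] = SPECIFIC_A
        elif poly_b:
            classes[pos] = SPECIFIC_B
        elif consensus_a[pos - 1] != consensus_b[pos - 1]:
            classes[pos] = FIXED
    return SiteClassification(classes, L)


def count_classes_by_region(cls: SiteClassification, regions: RegionMap) -> pd.DataFrame:
    """Per-region class counts (rows: region labels + 'total')."""
    labels = regions.labels
    rows = {lab: {c: 0 for c in CLASSES} for lab in labels + ["other"]}
    for pos, c in cls.classes.items():
        rows[regions.label_of(pos)][c] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    if (df.loc["other"] == 0).all():
        df = df.drop(index="other")
    df.loc["total"] = df.sum()
    df.index.name = "region"
    df.columns = [c.lower() for c in CLASSES]
    return df


def pearson_chi2(table: Sequence[Sequence[float]]) -> Tuple[float, int, float]:
    """Pearson chi-square without continuity correction; asymptotic p."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def chi2_power(effect_w: float, n_total: float, df: int, alpha: float = 0.05) -> float:
    """Power of the chi-square test at effect size w (noncentrality n*w^2)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if effect_w <= 0 or n_total <= 0:
        raise ValueError("effect_w and n_total must be positive")
    crit = stats.chi2.isf(alpha, df)
    lam = n_total * effect_w ** 2
    return float(stats.ncx2.sf(crit, df, lam))


@dataclass
class UniformityResult:
    ks_d: float
    ks_p: float
    chi2: float
    chi2_df: int
    chi2_p: float
    few_positions: bool = False


def position_uniformity(positions: Sequence[int], L: int,
                        bin_width: int = 300) -> UniformityResult:
    """Test whether site positions are uniform on [1, L].

    Continuous one-sample KS against Uniform(0, L) plus a Pearson chi-square
    over ``bin_width`` bins, the terminal short bin's expectation scaled by
    its length.
    """
    pos = np.asarray(positions, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if pos.size and (pos.min() < 1 or pos.max() > L):
        raise ValueError("positions outside [1, L]")
    few = pos.size < 5
    if pos.size == 0:
        return UniformityResult(0.0, 1.0, 0.0, 0, 1.0, True)
    ks = stats.kstest(pos, "uniform", args=(0, L))
    edges = list(range(0, L, bin_width)) + [L]
    widths = np.diff(edges).astype(float)
    obs, _ = np.histogram(pos, bins=edges)
    exp = pos.size * widths / L
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(widths) - 1
    p = float(stats.chi2.sf(chi2, df))
    return UniformityResult(float(ks.statistic), float(ks.pvalue), chi2, df, p, few)


def write_class_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
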