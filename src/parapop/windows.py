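"""Sliding-window engine for diversity, neutrality and site-class tracks.

Windows are defined on the alignment frame (nucleotide coordinates), not
on segregating-site indices, matching DnaSP-style nucleotide windows.
Statistics in windows with no segregating sites are reported as NaN (and
written as empty TSV fields) rather than zero, to avoid spurious dips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .diversity import theta_pi_total_from_sites
from .neutrality import fay_wu_h, sfs_from_sites, tajimas_d
from .popdata import HaplotypeAlignment, SiteTable
from .site_classes import CLASSES, SiteClassification


@dataclass
class WindowSpec:
    width: int = 300
    step: int = 30
    edge_rule: str = "drop_partial"

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.width):
            raise ValueError("need 0 < step <= width")
        if self.edge_rule not in ("drop_partial", "truncate_last"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")


def make_windows(L: int, spec: WindowSpec) -> List[Tuple[int, int]]:
    """1-based closed windows: starts 1, 1+step, ...; see ``edge_rule``."""
    if L < spec.width:
        raise ValueError(f"L={L} shorter than window width {spec.width}")
    out = []
    start = 1
    while True:
        end = start + spec.width - 1
        if end <= L:
            out.append((start, end))
        else:
            if spec.edge_rule == "truncate_last" and start <= L:
                out.append((start, L))
            break
        start += spec.step
    return out


def window_track(sites: SiteTable,
                 classification: Optional[SiteClassification],
                 L: int,
                 spec: Optional[WindowSpec] = None,
                 n: Optional[int] = None) -> pd.DataFrame:
    """Per-window S, pi, Tajima's D, Fay & Wu's H and site-class counts.

    D and H are computed from the window's sites on the per-gene (total)
    scale; H needs polarized rows and is NaN where none fall in the window.
    """
    spec = spec or WindowSpec()
    n = n or sites.n
    rows = []
    for start, end in make_windows(L, spec):
        width = end - start + 1
        wsites = sites.in_intervals([(start, end)])
        S = wsites.S
        row = {"start": start, "end": end, "midpoint": (start + end) / 2.0, "S": S}
        if S > 0:
            tpt = theta_pi_total_from_sites(wsites)
            row["pi"] = tpt / width
            row["D"] = tajimas_d(S, tpt, n) if n >= 4 else np.nan
            sfs = sfs_from_sites(wsites)
            if sfs.S > 0:
                H, _, _ = fay_wu_h(sfs)
                row["H"] = H
            else:
                row["H"] = np.nan
        else:
            row["pi"] = 0.0
            row["D"] = np.nan
            row["H"] = np.nan
        if classification is not None:
            for cls in CLASSES:
                row[cls.lower()] = sum(
                    1 for p in classification.positions_of(cls) if start <= p <= end)
        rows.append(row)
    return pd.DataFrame(rows)


def write_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")
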