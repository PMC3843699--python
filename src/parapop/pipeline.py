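"""End-to-end analysis orchestration producing a summary-table-shaped report.

``run_full_analysis`` ties the modules together: read (or receive) the
gene-A haplotypes, the paralogue-B site data, outgroup, region map and
conversion tracts; call and polarize segregating sites; classify site
coexistence; compute per-region diversity and neutrality statistics;
contrast regions with chi-square; run sliding windows; and attach
simulation-based rejection probabilities under the neutral and
demographic nulls, with a conversion-masked rerun.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .coalsim import (DEFAULT_TRACTS, DemographyModel, SimConfig,
                      masked_rerun, rejection_report)
from .diversity import diversity_summary, theta_pi_total_from_sites
from .neutrality import neutrality_stats
from .popdata import (HaplotypeAlignment, Outgroup, RegionMap, SiteTable,
                      call_segregating_sites, collapse_haplotypes,
                      polarize_sites, subset_columns)
from .site_classes import (CLASSES, SiteClassification,
                           classify_paralogue_sites, count_classes_by_region,
                           pearson_chi2, position_uniformity)
from .windows import WindowSpec, window_track, write_track

log = logging.getLogger("parapop")


@dataclass
class AnalysisConfig:
    regions: RegionMap
    window: WindowSpec = field(default_factory=WindowSpec)
    demography: Optional[DemographyModel] = None
    replicates: int = 1000
    seed: int = 1
    maf_threshold: float = 0.0
    tracts: Sequence[Tuple[int, int]] = DEFAULT_TRACTS
    run_simulations: bool = True
    ew_reps: int = 1000


@dataclass
class AnalysisReport:
    summary: pd.DataFrame              # per-region diversity + neutrality
    class_counts: pd.DataFrame
    chi2_contrasts: pd.DataFrame
    windows: pd.DataFrame
    uniformity: Dict[str, float]
    rejection: Optional[pd.DataFrame] = None
    masked_rejection: Optional[pd.DataFrame] = None
    masked_S: Optional[int] = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.class_counts.to_csv(out / "class_counts.tsv", sep="\t")
        self.chi2_contrasts.to_csv(out / "chi2_contrasts.tsv", sep="\t", index=False)
        write_track(self.windows, out / "windows.tsv")
        pd.DataFrame([self.uniformity]).to_csv(out / "uniformity.tsv",
                                               sep="\t", index=False)
        if self.rejection is not None:
            self.rejection.to_csv(out / "rejection.tsv", sep="\t", index=False)
        if self.masked_rejection is not None:
            self.masked_rejection.to_csv(out / "rejection_masked.tsv",
                                         sep="\t", index=False)


def _region_frames(aln: HaplotypeAlignment, regions: RegionMap
                   ) -> Dict[str, Tuple[HaplotypeAlignment, int]]:
    frames = {"full": (aln, aln.L)}
    for label in regions.labels:
        sub = subset_columns(aln, regions.intervals_for(label), "keep")
        frames[label] = (sub, regions.length(label))
    return frames


def run_full_analysis(aln_a: HaplotypeAlignment,
                      sites_b: SiteTable,
                      consensus_a: str,
                      consensus_b: str,
                      outgroup: Outgroup,
                      cfg: AnalysisConfig) -> AnalysisReport:
    rng = np.random.default_rng(cfg.seed)
    log.info("parapop %s | seed=%d replicates=%d maf=%.3g",
             __version__, cfg.seed, cfg.replicates, cfg.maf_threshold)

    sites_a = call_segregating_sites(aln_a, cfg.maf_threshold).with_regions(cfg.regions)
    sites_a = polarize_sites(sites_a, outgroup)
    cls = classify_paralogue_sites(sites_a, consensus_a, sites_b, consensus_b,
                                   cfg.maf_threshold)
    class_counts = count_classes_by_region(cls, cfg.regions)

    # chi-square contrasts of (fixed, shared, specific_a) between region pairs
    labels = cfg.regions.labels
    contrast_rows = []
    trio = ["fixed", "shared", "specific_a"]
    totals = class_counts.loc["total", trio]
    for lab in labels:
        rest = totals - class_counts.loc[lab, trio]
        try:
            chi2, df, p = pearson_chi2([class_counts.loc[lab, trio].tolist(),
                                        rest.tolist()])
            contrast_rows.append({"contrast": f"{lab} vs rest", "chi2": chi2,
                                  "df": df, "p": p})
        except ValueError:
            pass
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            try:
                chi2, df, p = pearson_chi2([class_counts.loc[la, trio].tolist(),
                                            class_counts.loc[lb, trio].tolist()])
                contrast_rows.append({"contrast": f"{la} vs {lb}", "chi2": chi2,
                                      "df": df, "p": p})
            except ValueError:
                pass
    chi2_contrasts = pd.DataFrame(contrast_rows)

    # per-region summaries
    frames = _region_frames(aln_a, cfg.regions)
    summary_rows = []
    region_tables: Dict[str, SiteTable] = {}
    for label, (sub, length) in frames.items():
        sub_sites = (sites_a if label == "full"
                     else sites_a.in_intervals(cfg.regions.intervals_for(label)))
        region_tables[label] = sub_sites
        ds = diversity_summary(sub, sub_sites, length=length)
        hap_counts = [c for _, c in collapse_haplotypes(sub)]
        ns = neutrality_stats(sub_sites, hap_counts, ew_reps=cfg.ew_reps, rng=rng)
        summary_rows.append({
            "region": label, "length": length, "S": ds.S, "k": ds.k,
            "HHe": ds.HHe, "HHe_sd": ds.HHe_sd, "pi": ds.pi,
            "theta_w": ds.theta_w, "D": ns.D, "Fs": ns.Fs, "H": ns.H,
            "nH": ns.nH, "EW_F": ns.EW_F, "EW_p": ns.EW_p_lower,
            "fixed": class_counts.loc[label, "fixed"] if label in class_counts.index else class_counts.loc["total", "fixed"],
            "shared": class_counts.loc[label, "shared"] if label in class_counts.index else class_counts.loc["total", "shared"],
            "specific_a": class_counts.loc[label, "specific_a"] if label in class_counts.index else class_counts.loc["total", "specific_a"],
        })
    summary = pd.DataFrame(summary_rows)

    uni = position_uniformity(sites_a.positions, aln_a.L,
                              bin_width=cfg.window.width)
    uniformity = {"ks_d": uni.ks_d, "ks_p": uni.ks_p,
                  "chi2": uni.chi2, "chi2_p": uni.chi2_p}

    wins = window_track(sites_a, cls, aln_a.L, cfg.window)

    rejection = masked = None
    masked_S = None
    if cfg.run_simulations:
        demography = cfg.demography or DemographyModel.european_default()
        sim = SimConfig(n=aln_a.n, replicates=cfg.replicates, seed=cfg.seed,
                        fixed_S=max(sites_a.S, 1))
        hap_counts = [c for _, c in collapse_haplotypes(aln_a)]
        rej_frames = []
        for model_label, dem in (("neutral", DemographyModel.constant(
                demography.epochs[-1].ne_start)), ("demography", demography)):
            rep = rejection_report(sites_a, hap_counts, sim, dem, model_label)
            rej_frames.append(rep.to_frame())
        rejection = pd.concat(rej_frames, ignore_index=True)
        aln_masked = subset_columns(aln_a, list(cfg.tracts), "drop")
        hap_masked = [c for _, c in collapse_haplotypes(aln_masked)]
        masked_sites, mrep = masked_rerun(sites_a, hap_masked, list(cfg.tracts),
                                          sim, demography, frame_length=aln_a.L)
        masked = mrep.to_frame()
        masked_S = masked_sites.S
        log.info("masked rerun: S %d -> %d", sites_a.S, masked_S)

    return AnalysisReport(summary=summary, class_counts=class_counts,
                          chi2_contrasts=chi2_contrasts, windows=wins,
                          uniformity=uniformity, rejection=rejection,
                          masked_rejection=masked, masked_S=masked_S)
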