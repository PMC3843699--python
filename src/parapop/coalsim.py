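"""Coalescent simulation under piecewise demography and simulation-based
rejection probabilities.

Time runs backwards in generations. A demography is a contiguous list of
epochs, each constant-size or exponential (``N(t) = Ne_start *
exp(-growth*(t-start))`` within the epoch). Coalescence times are drawn by
inverting the cumulative pair-coalescence intensity, which is closed-form
in both epoch types, so the simulator is exact.

The null used for rejection probabilities conditions on the observed
number of segregating sites (fixed-S): exactly S mutations are placed on
the genealogy proportionally to branch length (infinite sites). A theta
mode (Poisson mutations) is provided for calibration checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .neutrality import SFS, fay_wu_h, fus_fs, tajimas_d, zeng_nh
from .popdata import SiteTable


@dataclass
class Epoch:
    start_gen: float
    end_gen: float  # math.inf for the terminal epoch
    ne_start: float
    growth: float = 0.0  # per-generation backward rate; N(t)=ne_start*exp(-growth*(t-start))

    def ne_at(self, t: float) -> float:
        return self.ne_start * math.exp(-self.growth * (t - self.start_gen))

    def intensity(self, t0: float, t1: float) -> float:
        """Integral of 1/(2N(s)) ds over [t0, t1] within this epoch."""
        if self.growth == 0.0:
            return (t1 - t0) / (2.0 * self.ne_start)
        g = self.growth
        return (math.exp(g * (t1 - self.start_gen))
                - math.exp(g * (t0 - self.start_gen))) / (2.0 * self.ne_start * g)

    def invert(self, t0: float, target: float) -> float:
        """t >= t0 inside the epoch with intensity(t0, t) = target (may exceed end)."""
        if self.growth == 0.0:
            return t0 + 2.0 * self.ne_start * target
        g = self.growth
        val = math.exp(g * (t0 - self.start_gen)) + 2.0 * self.ne_start * g * target
        return self.start_gen + math.log(val) / g


@dataclass
class DemographyModel:
    epochs: List[Epoch]
    generation_time_years: float = 25.0

    def __post_init__(self) -> None:
        t = 0.0
        for e in self.epochs:
            if not math.isclose(e.start_gen, t):
                raise ValueError("epochs must be contiguous from 0")
            if e.ne_start <= 0:
                raise ValueError("Ne must be positive")
            t = e.end_gen
        if not math.isinf(self.epochs[-1].end_gen):
            raise ValueError("terminal epoch must extend to infinity")

    @classmethod
    def constant(cls, ne: float, generation_time_years: float = 25.0) -> "DemographyModel":
        return cls([Epoch(0.0, math.inf, ne)], generation_time_years)

    @classmethod
    def european_default(cls,
                         ne_present: float = 10_000.0,
                         ne_bottleneck: float = 1_861.0,
                         ne_ancestral: float = 10_000.0,
                         bottleneck_start_years: float = 51_000.0,
                         bottleneck_end_years: float = 21_000.0,
                         generation_time_years: float = 25.0) -> "DemographyModel":
        """Bottleneck (Ne=1861, 51-21 kya) followed by exponential growth to
        the present; ancestral size before the bottleneck.

        Present-day and ancestral sizes and the generation time are not part
        of the published model and are exposed as parameters.
        """
        t_end = bottleneck_end_years / generation_time_years      # 840 gen
        t_start = bottleneck_start_years / generation_time_years  # 2040 gen
        growth = math.log(ne_present / ne_bottleneck) / t_end
        return cls([
            Epoch(0.0, t_end, ne_present, growth),
            Epoch(t_end, t_start, ne_bottleneck, 0.0),
            Epoch(t_start, math.inf, ne_ancestral, 0.0),
        ], generation_time_years)

    def epoch_at(self, t: float) -> int:
        for i, e in enumerate(self.epochs):
            if t < e.end_gen:
                return i
        return len(self.epochs) - 1

    def sample_coal_time(self, t0: float, k: int, rng: np.random.Generator) -> float:
        """Next coalescence time for k lineages starting from t0."""
        pair_rate = k * (k - 1) / 2.0
        target = rng.exponential() / pair_rate
        t = t0
        i = self.epoch_at(t0)
        while True:
            e = self.epochs[i]
            end = e.end_gen
            avail = e.intensity(t, end) if not math.isinf(end) else math.inf
            if target <= avail:
                return e.invert(t, target)
            target -= avail
            t = end
            i += 1

    def to_text(self) -> str:
        lines = [f"generation_time_years\t{self.generation_time_years}"]
        for e in self.epochs:
            end = "inf" if math.isinf(e.end_gen) else f"{e.end_gen:g}"
            lines.append(f"epoch\t{e.start_gen:.17g}\t{end}\t{e.ne_start:.17g}\t{e.growth:.17g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DemographyModel":
        gen_time = 25.0
        epochs = []
        for line in text.splitlines():
            parts = line.strip().split("\t")
            if not parts or not parts[0]:
                continue
            if parts[0] == "generation_time_years":
                gen_time = float(parts[1])
            elif parts[0] == "epoch":
                end = math.inf if parts[2] == "inf" else float(parts[2])
                epochs.append(Epoch(float(parts[1]), end, float(parts[3]), float(parts[4])))
        return cls(epochs, gen_time)


@dataclass
class Genealogy:
    """Binary coalescent tree: nodes 0..n-1 are leaves; 2n-2 is the root."""

    n: int
    parent: np.ndarray        # parent[node]; root's parent = -1
    node_time: np.ndarray     # in generations
    children: List[Tuple[int, int]]  # per internal node (offset n)

    @property
    def num_nodes(self) -> int:
        return 2 * self.n - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        root = self.num_nodes - 1
        bl = np.zeros(self.num_nodes - 1)
        for v in range(self.num_nodes - 1):
            bl[v] = self.node_time[self.parent[v]] - self.node_time[v]
        return bl

    def leaves_below(self) -> np.ndarray:
        nl = np.zeros(self.num_nodes, dtype=int)
        nl[:self.n] = 1
        for i, (a, b) in enumerate(self.children):
            nl[self.n + i] = nl[a] + nl[b]
        return nl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.node_time[-1])


def simulate_genealogy(n: int, demography: DemographyModel,
                       rng: np.random.Generator) -> Genealogy:
    if n < 2:
        raise ValueError("need n >= 2")
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    children: List[Tuple[int, int]] = []
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t = demography.sample_coal_time(t, k, rng)
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        children.append((a, b))
        active = [x for x in active if x not in (a, b)]
        active.append(nxt)
        nxt += 1
    return Genealogy(n=n, parent=parent, node_time=node_time, children=children)


@dataclass
class MutationResult:
    sfs: SFS
    hap_counts: List[int]          # multiplicities of distinct haplotypes
    mutated_branches: List[int]

    @property
    def k(self) -> int:
        return len(self.hap_counts)


def _haplotype_partition(tree: Genealogy, branch_hits: np.ndarray) -> List[int]:
    """Distinct-haplotype multiplicities given which branches carry mutations."""
    n = tree.n
    # signature of each node = frozenset of mutated branches on root path;
    # build top-down so each node extends its parent's signature
    root = tree.num_nodes - 1
    node_sig: List[Optional[Tuple]] = [None] * tree.num_nodes
    node_sig[root] = ()
    for idx in range(len(tree.children) - 1, -1, -1):
        node = n + idx
        for ch in tree.children[idx]:
            node_sig[ch] = node_sig[node] + ((ch,) if branch_hits[ch] else ())
    from collections import Counter
    ctr = Counter(tuple(sorted(node_sig[leaf])) for leaf in range(n))
    return sorted(ctr.values(), reverse=True)


def mutate_fixed_s(tree: Genealogy, S: int, rng: np.random.Generator) -> MutationResult:
    """Place exactly S infinite-sites mutations proportional to branch length."""
    n = tree.n
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return MutationResult(SFS(n, np.zeros(n - 1)), [n], [])
    bl = tree.branch_lengths()
    w = bl / bl.sum()
    branches = rng.choice(len(bl), size=S, p=w)
    nl = tree.leaves_below()
    xi = np.zeros(n - 1)
    hits = np.zeros(tree.num_nodes, dtype=bool)
    for b in branches:
        xi[nl[b] - 1] += 1
        hits[b] = True
    hap_counts = _haplotype_partition(tree, hits)
    return MutationResult(SFS(n, xi), hap_counts, list(map(int, branches)))


def mutate_theta(tree: Genealogy, theta: float, ne_ref: float,
                 rng: np.random.Generator) -> MutationResult:
    """Poisson mutations at locus rate u = theta/(4*ne_ref) per generation."""
    u = theta / (4.0 * ne_ref)
    total = tree.total_branch_length()
    S = int(rng.poisson(u * total))
    return mutate_fixed_s(tree, S, rng)


@dataclass
class SimConfig:
    n: int
    replicates: int = 10_000
    seed: int = 0
    fixed_S: Optional[int] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.replicates < 1:
            raise ValueError("invalid SimConfig")
        if (self.fixed_S is None) == (self.theta is None):
            raise ValueError("set exactly one of fixed_S / theta")


def simulate_replicates(config: SimConfig, demography: DemographyModel) -> pd.DataFrame:
    """Replicate table of D, Fs, H, nH, k, S (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    ne_ref = demography.epochs[0].ne_start
    rows = []
    for _ in range(config.replicates):
        tree = simulate_genealogy(config.n, demography, rng)
        if config.fixed_S is not None:
            mut = mutate_fixed_s(tree, config.fixed_S, rng)
        else:
            mut = mutate_theta(tree, config.theta, ne_ref, rng)
        sfs = mut.sfs
        tpt = sfs.theta_pi()
        S = sfs.S
        H, _, _ = fay_wu_h(sfs)
        rows.append({
            "S": S,
            "k": mut.k,
            "theta_pi": tpt,
            "D": tajimas_d(S, tpt, config.n) if S >= 1 else np.nan,
            "Fs": fus_fs(config.n, mut.k, tpt) if tpt > 0 else np.nan,
            "H": H,
            "nH": zeng_nh(sfs) if S >= 1 else np.nan,
            "tmrca": tree.tmrca(),
            "total_length": tree.total_branch_length(),
        })
    return pd.DataFrame(rows)


def rejection_probability(observed: float, replicate_values: Sequence[float],
                          tail: str = "lower") -> float:
    """Add-one one-tailed Monte-Carlo p-value of the observed statistic."""
    vals = np.asarray([v for v in replicate_values if np.isfinite(v)])
    if vals.size < 100:
        raise ValueError("need at least 100 finite replicates")
    if tail == "lower":
        hits = int((vals <= observed).sum())
    elif tail == "upper":
        hits = int((vals >= observed).sum())
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + hits) / (vals.size + 1)


DEFAULT_TRACTS: Tuple[Tuple[int, int], ...] = ((624, 634), (3080, 3186))


@dataclass
class RejectionReport:
    model: str
    replicates: int
    observed: Dict[str, float]
    p_values: Dict[str, float]
    S_used: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": s, "observed": self.observed[s],
                 "rejection_p": self.p_values.get(s, np.nan),
                 "model": self.model, "replicates": self.replicates}
                for s in self.observed]
        return pd.DataFrame(rows)


_TAILS = {"D": "lower", "Fs": "lower", "H": "lower", "nH": "lower"}


def rejection_report(sites: SiteTable, hap_counts: Sequence[int],
                     config: SimConfig, demography: DemographyModel,
                     model_label: str = "demography") -> RejectionReport:
    """One-tailed rejection probabilities for D, Fs, H, nH of an observed
    region against a simulated null conditioned on the observed S."""
    from .neutrality import neutrality_stats
    rng = np.random.default_rng(config.seed)
    obs = neutrality_stats(sites, list(hap_counts), rng=rng)
    S = int(sites.S)
    cfg = SimConfig(n=sites.n, replicates=config.replicates,
                    seed=config.seed, fixed_S=S)
    reps = simulate_replicates(cfg, demography)
    observed = {"D": obs.D, "Fs": obs.Fs, "H": obs.H, "nH": obs.nH}
    pvals = {}
    for stat, tail in _TAILS.items():
        if np.isfinite(observed[stat]):
            pvals[stat] = rejection_probability(observed[stat], reps[stat], tail)
    return RejectionReport(model=model_label, replicates=config.replicates,
                           observed=observed, p_values=pvals, S_used=S)


def masked_rerun(sites: SiteTable, hap_counts_masked: Sequence[int],
                 tracts: Sequence[Tuple[int, int]],
                 config: SimConfig, demography: DemographyModel,
                 frame_length: Optional[int] = None) -> Tuple[SiteTable, RejectionReport]:
    """Drop sites inside conversion tracts and recompute the rejection report
    with the reduced S feeding the fixed-S null."""
    L = frame_length or max(sites.positions, default=0)
    for a, b in tracts:
        if a < 1 or (L and a > L):
            raise ValueError(f"tract [{a}, {b}] outside frame")
    masked = sites.drop_intervals(list(tracts))
    report = rejection_report(masked, hap_counts_masked, config, demography,
                              model_label="demography+masked")
    return masked, report


def write_ms_like(results: Sequence[MutationResult], path, positions_L: int = 1) -> None:
    """Minimal ms-style text output (``//``, ``segsites:``, ``positions:``)."""
    with open(path, "w") as fh:
        fh.write("parapop coalsim\n\n")
        for res in results:
            fh.write("//\n")
            S = int(res.sfs.S)
            fh.write(f"segsites: {S}\n")
            if S:
                pos = " ".join(f"{(i + 0.5) / S:.5f}" for i in range(S))
                fh.write(f"positions: {pos}\n")
            fh.write("\n")
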