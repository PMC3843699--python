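"""Synthetic paralogue datasets with known per-region site-class structure.

The generator emulates the statistical anatomy of a duplicated human gene
pair sampled from one population: a functional gene A sequenced as n
haplotypes collapsing to a smaller number of distinct variants, a
paralogous pseudogene B known from an external polymorphism table, an
outgroup carrying ancestral alleles, and a region map (an intron-2-like
conversion-suppressed subregion, a coding block, remaining non-coding
sequence). Site classes (FIXED between paralogue consensuses, SHARED,
SPECIFIC to either gene) are planted directly at configured per-region
counts, so the classifier's recovery of the truth table is exact by
construction and is itself the test. Derived-allele counts are drawn from
the neutral spectrum P(i) proportional to 1/i, or from a
high-frequency-skewed mixture emulating genetic hitchhiking in a chosen
region.

Two conversion-tract landmarks are built in when the targets allow: four
adjacent gene-A sites inside positions 624-634 and six sites at 3080 and
3102-3186, mirroring the minimum tracts the masking step consumes by
default. Coding-region polymorphisms are planted with controlled
synonymous/nonsynonymous roles so that the distinct protein-variant count
of the sample is exact (default 6 proteins from 4 amino-acid-changing
sites among 33 haplotype variants).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .coalsim import DemographyModel, Genealogy, mutate_fixed_s, simulate_genealogy
from .diversity import translate_codon
from .popdata import HaplotypeAlignment, Outgroup, RegionMap, SiteTable
from .site_classes import (FIXED, INVARIANT, SHARED, SPECIFIC_A, SPECIFIC_B,
                           SiteClassification)

_BASES = "ACGT"
_DEF_REGIONS = (("noncds", 1, 623), ("intron2", 624, 905),
                ("cds", 906, 2393), ("noncds", 2394, 3357))
_DEF_TARGETS = {
    "intron2": {"fixed": 17, "shared": 1, "specific_a": 11, "specific_b": 2},
    "noncds": {"fixed": 5, "shared": 3, "specific_a": 18, "specific_b": 8},
    "cds": {"fixed": 5, "shared": 6, "specific_a": 5, "specific_b": 5},
}
TRACT_INTRON2 = (624, 634)
TRACT_UTR = (3080, 3186)
_UTR_INNER = (3102, 3186)


@dataclass
class SynthConfig:
    L: int = 3357
    regions: Optional[RegionMap] = None
    n_A: int = 64
    n_B: int = 50
    targets: Optional[Dict[str, Dict[str, int]]] = None
    sfs_mode: str = "neutral"            # or "sweep_skewed"
    sweep_region: str = "intron2"
    conversion_suppressed_region: str = "intron2"
    distinct_haplotype_target: int = 33
    nonsyn_cds_sites: int = 4
    protein_variant_target: int = 6
    outgroup_cds_divergence: Tuple[int, int] = (12, 4)   # (syn, nonsyn)
    outgroup_noncds_divergence: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            self.regions = RegionMap(list(_DEF_REGIONS))
        if self.targets is None:
            self.targets = {k: dict(v) for k, v in _DEF_TARGETS.items()}
        for reg, t in self.targets.items():
            if any(v < 0 for v in t.values()):
                raise ValueError("negative site-class target")
            if sum(t.values()) > self.regions.length(reg):
                raise ValueError(f"targets for {reg!r} exceed region capacity")
        if self.sfs_mode not in ("neutral", "sweep_skewed"):
            raise ValueError(f"unknown sfs_mode {self.sfs_mode!r}")
        if not (1 <= self.distinct_haplotype_target <= self.n_A):
            raise ValueError("distinct_haplotype_target must be in [1, n_A]")


@dataclass
class TruthTable:
    frame: pd.DataFrame  # columns: position, cls, region, derived_count

    def class_of(self, position: int) -> str:
        hit = self.frame[self.frame.position == position]
        return hit.cls.iloc[0] if len(hit) else INVARIANT

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class ParalogueDataset:
    aln_a: HaplotypeAlignment
    aln_b: HaplotypeAlignment
    outgroup: Outgroup
    truth: TruthTable
    config: SynthConfig
    consensus_a: str   # ancestral sequence (gene-A consensus at monomorphic sites)
    consensus_b: str


class _RetryGeneration(Exception):
    pass


def _partition(n: int, k: int) -> List[int]:
    """Skewed deterministic partition of n chromosomes into k variant
    multiplicities: the surplus above one-per-variant is allocated by
    repeated halving, leaving a realistic few common and many rare types."""
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    counts = [1] * k
    remaining = n - k
    i = 0
    while remaining > 0:
        add = max(1, remaining // 2)
        counts[i % k] += add
        remaining -= add
        i += 1
    return sorted(counts, reverse=True)


def _neutral_count(n: int, rng: np.random.Generator) -> int:
    i = np.arange(1, n)
    w = 1.0 / i
    return int(rng.choice(i, p=w / w.sum()))


def _sweep_count(n: int, rng: np.random.Generator) -> int:
    """High-frequency-derived excess: 80% mass within 8 copies of fixation."""
    if rng.random() < 0.8:
        return int(rng.integers(max(n - 8, 1), n))
    return _neutral_count(n, rng)


def _greedy_carriers(counts: Sequence[int], target: int,
                     rng: np.random.Generator) -> List[int]:
    """Variant indices whose multiplicities greedily approximate ``target``
    derived chromosomes without exceeding it (always at least one variant)."""
    order = list(rng.permutation(len(counts)))
    sel: List[int] = []
    s = 0
    for v in order:
        c = counts[v]
        if s + c <= target:
            sel.append(int(v))
            s += c
    if not sel:
        sel = [int(min(order, key=lambda v: counts[v]))]
    return sel


def _syn_change(cds: str, pos0: int) -> Optional[str]:
    ci, off = divmod(pos0, 3)
    cod = cds[3 * ci:3 * ci + 3]
    aa = translate_codon(cod)
    for b in _BASES:
        if b != cod[off] and translate_codon(cod[:off] + b + cod[off + 1:]) == aa:
            return b
    return None


def _nonsyn_change(cds: str, pos0: int) -> Optional[str]:
    ci, off = divmod(pos0, 3)
    cod = cds[3 * ci:3 * ci + 3]
    aa = translate_codon(cod)
    for b in _BASES:
        if b == cod[off]:
            continue
        aa2 = translate_codon(cod[:off] + b + cod[off + 1:])
        if aa2 not in (aa, "*"):
            return b
    return None


_SAFE_CODONS = [a + b + d for a in _BASES for b in _BASES for d in _BASES
                if translate_codon(a + b + d) not in (None, "*")]


def _random_ancestral(cfg: SynthConfig, rng: np.random.Generator) -> str:
    seq = list(rng.choice(list(_BASES), size=cfg.L))
    for a, b in cfg.regions.intervals_for("cds"):
        span = b - a + 1
        ncod = span // 3
        block = "".join(_SAFE_CODONS[i]
                        for i in rng.choice(len(_SAFE_CODONS), size=ncod))
        block += "".join(rng.choice(list(_BASES), size=span - 3 * ncod))
        seq[a - 1:b] = list(block)
    return "".join(seq)


def _other_base(b: str, rng: np.random.Generator) -> str:
    return str(rng.choice([x for x in _BASES if x != b]))


def generate_paralogue_dataset(cfg: Optional[SynthConfig] = None) -> ParalogueDataset:
    """Generate gene-A haplotypes, pseudogene-B haplotypes, an outgroup and
    the truth table, with planted per-region site-class counts.

    Deterministic given ``cfg.seed``; internally retries sub-seeds until the
    distinct-haplotype and protein-variant constraints hold exactly.
    """
    cfg = cfg or SynthConfig()
    master = np.random.default_rng(cfg.seed)
    for _ in range(80):
        rng = np.random.default_rng(master.integers(2 ** 63))
        try:
            return _generate_once(cfg, rng)
        except _RetryGeneration:
            continue
    raise RuntimeError("failed to generate a dataset satisfying all constraints")


def _generate_once(cfg: SynthConfig, rng: np.random.Generator) -> ParalogueDataset:
    regions = cfg.regions
    tgt = cfg.targets
    ancestral = _random_ancestral(cfg, rng)
    cds_iv = regions.intervals_for("cds")
    cds_seq = "".join(ancestral[a - 1:b] for a, b in cds_iv)

    def cds_offset(pos: int) -> int:
        off = 0
        for a, b in cds_iv:
            if a <= pos <= b:
                return off + (pos - a)
            off += b - a + 1
        raise ValueError(f"{pos} not in cds")

    used: Set[int] = set()
    placement: List[Tuple[int, str, str]] = []
    a_site_mut: Dict[int, str] = {}
    fixed_mut: Dict[int, str] = {}
    b_site_mut: Dict[int, str] = {}
    nonsyn_positions: List[int] = []

    def pool(region: str, exclude: Sequence[Tuple[int, int]] = ()) -> List[int]:
        out = []
        for a, b in regions.intervals_for(region):
            for p in range(a, b + 1):
                if p not in used and not any(x <= p <= y for x, y in exclude):
                    out.append(p)
        return out

    def take(positions: List[int], m: int) -> List[int]:
        if m <= 0:
            return []
        if len(positions) < m:
            raise _RetryGeneration()
        picked = sorted(int(p) for p in rng.choice(positions, size=m, replace=False))
        used.update(picked)
        return picked

    def plant_a(p: int, cls_name: str, region: str, base: Optional[str] = None) -> None:
        placement.append((p, cls_name, region))
        mut = base if base is not None else _other_base(ancestral[p - 1], rng)
        a_site_mut[p] = mut
        if cls_name == SHARED:
            b_site_mut[p] = mut

    def plant_other(p: int, cls_name: str, region: str) -> None:
        placement.append((p, cls_name, region))
        if cls_name == FIXED:
            fixed_mut[p] = _other_base(ancestral[p - 1], rng)
        else:
            b_site_mut[p] = _other_base(ancestral[p - 1], rng)

    # ---- intron-2-like region: tract sites first --------------------------
    n_spec_i2 = tgt.get("intron2", {}).get("specific_a", 0)
    in_tract = min(4, n_spec_i2)
    tract_pool = [p for p in pool("intron2")
                  if TRACT_INTRON2[0] <= p <= TRACT_INTRON2[1]]
    for p in take(tract_pool, in_tract):
        plant_a(p, SPECIFIC_A, "intron2")
    for p in take(pool("intron2", exclude=[TRACT_INTRON2]), n_spec_i2 - in_tract):
        plant_a(p, SPECIFIC_A, "intron2")
    for p in take(pool("intron2", exclude=[TRACT_INTRON2]),
                  tgt.get("intron2", {}).get("shared", 0)):
        plant_a(p, SHARED, "intron2")
    for cls_name, key in ((FIXED, "fixed"), (SPECIFIC_B, "specific_b")):
        for p in take(pool("intron2", exclude=[TRACT_INTRON2]),
                      tgt.get("intron2", {}).get(key, 0)):
            plant_other(p, cls_name, "intron2")

    # ---- non-cds: six-site UTR-like tract, remainder outside both tracts --
    n_spec_nc = tgt.get("noncds", {}).get("specific_a", 0)
    n_shared_nc = tgt.get("noncds", {}).get("shared", 0)
    spec_in_tract = 0
    if n_spec_nc >= 1 and TRACT_UTR[0] not in used:
        used.add(TRACT_UTR[0])
        plant_a(TRACT_UTR[0], SPECIFIC_A, "noncds")
        spec_in_tract = 1
    inner_pool = [q for q in pool("noncds") if _UTR_INNER[0] <= q <= _UTR_INNER[1]]
    shared_in = min(n_shared_nc, 3) if spec_in_tract else 0
    extra_spec_in = min(2, n_spec_nc - spec_in_tract) if spec_in_tract else 0
    inner = take(inner_pool, shared_in + extra_spec_in)
    for p in inner[:shared_in]:
        plant_a(p, SHARED, "noncds")
    for p in inner[shared_in:]:
        plant_a(p, SPECIFIC_A, "noncds")
    spec_in_tract += extra_spec_in
    out_pool = lambda: pool("noncds", exclude=[TRACT_UTR])
    for p in take(out_pool(), n_spec_nc - spec_in_tract):
        plant_a(p, SPECIFIC_A, "noncds")
    for p in take(out_pool(), n_shared_nc - shared_in):
        plant_a(p, SHARED, "noncds")
    for cls_name, key in ((FIXED, "fixed"), (SPECIFIC_B, "specific_b")):
        for p in take(out_pool(), tgt.get("noncds", {}).get(key, 0)):
            plant_other(p, cls_name, "noncds")

    # ---- cds: controlled synonymous/nonsynonymous roles -------------------
    n_spec_cds = tgt.get("cds", {}).get("specific_a", 0)
    n_nonsyn = min(cfg.nonsyn_cds_sites, n_spec_cds)
    cand = pool("cds")
    rng.shuffle(cand)
    for p in cand:
        if len(nonsyn_positions) == n_nonsyn:
            break
        b = _nonsyn_change(cds_seq, cds_offset(p))
        if b is not None:
            used.add(p)
            nonsyn_positions.append(p)
            plant_a(p, SPECIFIC_A, "cds", base=b)
    if len(nonsyn_positions) < n_nonsyn:
        raise _RetryGeneration()
    nonsyn_positions.sort()

    def take_cds_syn(m: int) -> List[int]:
        got: List[int] = []
        cand2 = pool("cds")
        rng.shuffle(cand2)
        for p in cand2:
            if len(got) == m:
                break
            b = _syn_change(cds_seq, cds_offset(p))
            if b is not None:
                used.add(p)
                got.append((p, b))
        if len(got) < m:
            raise _RetryGeneration()
        return got

    for p, b in take_cds_syn(n_spec_cds - n_nonsyn):
        plant_a(p, SPECIFIC_A, "cds", base=b)
    for p, b in take_cds_syn(tgt.get("cds", {}).get("shared", 0)):
        plant_a(p, SHARED, "cds", base=b)
    for cls_name, key in ((FIXED, "fixed"), (SPECIFIC_B, "specific_b")):
        for p in take(pool("cds"), tgt.get("cds", {}).get(key, 0)):
            plant_other(p, cls_name, "cds")

    # ---- gene-A haplotype structure ---------------------------------------
    k = cfg.distinct_haplotype_target
    counts = _partition(cfg.n_A, k)
    a_poly = sorted(a_site_mut)
    sweep = cfg.sfs_mode == "sweep_skewed"

    # protein patterns over the nonsynonymous sites: reference, singles,
    # and doubles as needed, carried by the lowest-multiplicity variants
    patterns: List[Tuple[int, ...]] = [tuple()]
    patterns += [(j,) for j in range(len(nonsyn_positions))]
    j = 0
    while len(patterns) < cfg.protein_variant_target and len(nonsyn_positions) >= 2:
        pair = (j % len(nonsyn_positions),
                (j + len(nonsyn_positions) - 1) % len(nonsyn_positions))
        if pair[0] != pair[1] and tuple(sorted(pair)) not in patterns:
            patterns.append(tuple(sorted(pair)))
        j += 1
        if j > 20:
            break
    patterns = patterns[:max(cfg.protein_variant_target, 1)]
    pat_variants = list(range(k - (len(patterns) - 1), k))
    protein_carriers: Dict[int, List[int]] = {jj: [] for jj in range(len(nonsyn_positions))}
    for var, pat in zip(pat_variants, patterns[1:]):
        for jj in pat:
            protein_carriers[jj].append(var)
    if nonsyn_positions and any(not v for v in protein_carriers.values()):
        raise _RetryGeneration()  # every nonsyn site must be polymorphic

    carriers: Dict[int, List[int]] = {}
    for p in a_poly:
        if p in nonsyn_positions:
            carriers[p] = protein_carriers[nonsyn_positions.index(p)]
            continue
        region = regions.label_of(p)
        t = (_sweep_count(cfg.n_A, rng) if sweep and region == cfg.sweep_region
             else _neutral_count(cfg.n_A, rng))
        carriers[p] = _greedy_carriers(counts, t, rng)

    variant_seqs = []
    for v in range(k):
        s = list(ancestral)
        for p in a_poly:
            if v in carriers[p]:
                s[p - 1] = a_site_mut[p]
        variant_seqs.append("".join(s))
    if len(set(variant_seqs)) != k:
        raise _RetryGeneration()
    aln_a = HaplotypeAlignment(ids=[f"h{v+1:02d}" for v in range(k)],
                               seqs=variant_seqs, counts=counts)

    # exact protein-variant count check
    if nonsyn_positions:
        prots = set()
        for s in variant_seqs:
            c = "".join(s[a - 1:b] for a, b in cds_iv)
            prots.add(tuple(translate_codon(c[i:i + 3])
                            for i in range(0, 3 * (len(c) // 3), 3)))
        if len(prots) != len(patterns):
            raise _RetryGeneration()

    # ---- pseudogene B ------------------------------------------------------
    consensus_b = list(ancestral)
    for p, b in fixed_mut.items():
        consensus_b[p - 1] = b
    consensus_b = "".join(consensus_b)
    b_poly = sorted(b_site_mut)
    kb = min(15, cfg.n_B)
    counts_b = _partition(cfg.n_B, kb)
    seqs_b: Optional[List[str]] = None
    for _ in range(25):
        carriers_b = {p: _greedy_carriers(counts_b, _neutral_count(cfg.n_B, rng), rng)
                      for p in b_poly}
        trial = []
        for v in range(kb):
            s = list(consensus_b)
            for p in b_poly:
                if v in carriers_b[p]:
                    s[p - 1] = b_site_mut[p]
            trial.append("".join(s))
        if len(set(trial)) == kb or not b_poly:
            seqs_b = trial
            break
    if seqs_b is None:
        raise _RetryGeneration()
    aln_b = HaplotypeAlignment(ids=[f"p{v+1:02d}" for v in range(kb)],
                               seqs=seqs_b, counts=counts_b)

    # ---- outgroup: ancestral alleles plus planted divergence ---------------
    og = list(ancestral)
    n_syn_div, n_nonsyn_div = cfg.outgroup_cds_divergence
    got_syn = got_nonsyn = 0
    cand3 = pool("cds")
    rng.shuffle(cand3)
    for p in cand3:
        if got_syn >= n_syn_div and got_nonsyn >= n_nonsyn_div:
            break
        if got_syn < n_syn_div:
            b = _syn_change(cds_seq, cds_offset(p))
            if b is not None:
                og[p - 1] = b
                used.add(p)
                got_syn += 1
                continue
        if got_nonsyn < n_nonsyn_div:
            b = _nonsyn_change(cds_seq, cds_offset(p))
            if b is not None:
                og[p - 1] = b
                used.add(p)
                got_nonsyn += 1
    noncds_pool = (pool("noncds", exclude=[TRACT_UTR])
                   + pool("intron2", exclude=[TRACT_INTRON2]))
    for p in take(noncds_pool, min(cfg.outgroup_noncds_divergence, len(noncds_pool))):
        og[p - 1] = _other_base(ancestral[p - 1], rng)
    outgroup = Outgroup("".join(og), "outgroup_synthetic")

    rows = []
    for p, cls_name, region in sorted(placement):
        dc = (sum(counts[v] for v in carriers[p])
              if cls_name in (SPECIFIC_A, SHARED) else None)
        rows.append({"position": p, "cls": cls_name, "region": region,
                     "derived_count": dc})
    truth = TruthTable(pd.DataFrame(rows))
    return ParalogueDataset(aln_a=aln_a, aln_b=aln_b, outgroup=outgroup,
                            truth=truth, config=cfg,
                            consensus_a=ancestral, consensus_b=consensus_b)


# ---------------------------------------------------------------------------

def generate_neutral_dataset(n: int, S: int, demography: DemographyModel,
                             seed: int, L: int = 3357
                             ) -> Tuple[HaplotypeAlignment, Outgroup]:
    """Coalescent haplotypes materialized as sequences on a random frame,
    with the outgroup carrying the ancestral allele at every site."""
    rng = np.random.default_rng(seed)
    ancestral = "".join(rng.choice(list(_BASES), size=L))
    tree = simulate_genealogy(n, demography, rng)
    mut = mutate_fixed_s(tree, S, rng)
    positions = sorted(int(p) for p in rng.choice(np.arange(1, L + 1), size=S,
                                                  replace=False))
    leaf_sets = _leaf_sets(tree)
    seqs = [list(ancestral) for _ in range(n)]
    for pos, branch in zip(positions, mut.mutated_branches):
        derived = _other_base(ancestral[pos - 1], rng)
        for leaf in leaf_sets[branch]:
            seqs[leaf][pos - 1] = derived
    aln = HaplotypeAlignment(ids=[f"s{i+1:02d}" for i in range(n)],
                             seqs=["".join(s) for s in seqs], counts=[1] * n)
    return aln, Outgroup(ancestral, "outgroup_synthetic")


def _leaf_sets(tree: Genealogy) -> List[Set[int]]:
    sets: List[Set[int]] = [{leaf} for leaf in range(tree.n)]
    sets += [set() for _ in range(tree.n - 1)]
    for i, (a, b) in enumerate(tree.children):
        sets[tree.n + i] = sets[a] | sets[b]
    return sets


def recovery_report(truth: TruthTable, cls: SiteClassification
                    ) -> Tuple[pd.DataFrame, bool]:
    """Confusion matrix (truth class x called class) and an exact-match flag."""
    labels = [FIXED, SHARED, SPECIFIC_A, SPECIFIC_B, INVARIANT]
    conf = pd.DataFrame(0, index=labels, columns=labels)
    positions = set(truth.frame.position) | set(cls.classes)
    for p in sorted(positions):
        conf.loc[truth.class_of(p), cls.classes.get(p, INVARIANT)] += 1
    exact = bool(conf.values.sum() == np.trace(conf.values))
    return conf, exact


def dataset_site_tables(ds: ParalogueDataset, maf_threshold: float = 0.0
                        ) -> Tuple[SiteTable, SiteTable]:
    """Segregating-site tables of both paralogues, region-annotated."""
    from .popdata import call_segregating_sites
    sa = call_segregating_sites(ds.aln_a, maf_threshold).with_regions(ds.config.regions)
    sb = call_segregating_sites(ds.aln_b, maf_threshold).with_regions(ds.config.regions)
    return sa, sb
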