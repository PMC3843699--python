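"""Diversity summaries and coding-sequence selection statistics.

Nucleotide diversity pi is the average number of pairwise differences per
site, computed from site allele counts; haplotype heterozygosity HHe uses
Nei's unbiased estimator with its sampling variance. Coding statistics
follow Nei & Gojobori's (NG86) pathway counting: synonymous and
nonsynonymous site fractions per codon, pairwise proportions for piA/piS,
and Jukes-Cantor-corrected Ka/Ks against an outgroup, with a
McDonald-Kreitman contingency test of polymorphism versus divergence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

from .popdata import HaplotypeAlignment, SiteTable, call_segregating_sites, collapse_haplotypes

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon, '*' for stop, None if ambiguous."""
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.get(codon)


@dataclass
class DiversitySummary:
    S: int
    k: int
    HHe: float
    HHe_sd: float
    pi: float
    theta_w: float
    L_effective: int
    theta_pi_total: float


def haplotype_heterozygosity(counts: List[int]) -> Tuple[float, float]:
    """Nei's unbiased haplotype diversity and its sampling s.d."""
    n = sum(counts)
    if n < 2:
        raise ValueError("need n >= 2")
    p = np.asarray(counts, dtype=float) / n
    sp2 = float((p ** 2).sum())
    sp3 = float((p ** 3).sum())
    hhe = n / (n - 1) * (1.0 - sp2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sp3 - sp2 ** 2) + sp2 - sp2 ** 2)
    return hhe, math.sqrt(max(var, 0.0))


def theta_pi_total_from_sites(sites: SiteTable) -> float:
    """Sum over sites of the pairwise-difference probability (per gene)."""
    n = sites.n
    total = 0.0
    for r in sites:
        cs = list(r.counts.values())
        het = sum(a * b for a, b in itertools.combinations(cs, 2))
        total += 2.0 * het / (n * (n - 1))
    return total


def watterson_a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def diversity_summary(aln: HaplotypeAlignment, sites: Optional[SiteTable] = None,
                      length: Optional[int] = None) -> DiversitySummary:
    """Region-level diversity summary.

    ``length`` overrides the effective number of sites analyzed, which is
    needed when ``aln`` holds only segregating-site columns of a longer
    frame.
    """
    if aln.n < 2:
        raise ValueError("need n >= 2")
    if sites is None:
        sites = call_segregating_sites(aln, maf_threshold=0.0)
    L_eff = length if length is not None else aln.L
    spectrum = collapse_haplotypes(aln)
    hhe, sd = haplotype_heterozygosity([c for _, c in spectrum])
    tpt = theta_pi_total_from_sites(sites)
    a1 = watterson_a1(aln.n)
    return DiversitySummary(
        S=sites.S, k=len(spectrum), HHe=hhe, HHe_sd=sd,
        pi=tpt / L_eff, theta_w=sites.S / (a1 * L_eff),
        L_effective=L_eff, theta_pi_total=tpt)


# ---------------------------------------------------------------------------
# NG86 synonymous/nonsynonymous machinery

def codon_site_fractions(codon: str) -> Tuple[float, float]:
    """NG86 (syn_sites, nonsyn_sites) for one codon; they sum to 3.

    Changes producing a stop codon count as nonsynonymous.
    """
    aa = translate_codon(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if translate_codon(mut) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_pair_differences(c1: str, c2: str) -> Tuple[float, float]:
    """NG86 (syn_diffs, nonsyn_diffs) between two codons, averaging over all
    mutational pathways; pathways through stop codons are excluded when any
    stop-free pathway exists."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            aa_from, aa_to = translate_codon(cur), translate_codon(nxt)
            if aa_to == "*" or aa_from == "*":
                through_stop = True
            if aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    clean = [(s, d) for stop, s, d in paths if not stop]
    use = clean if clean else [(s, d) for _, s, d in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(d for _, d in use) / len(use)
    return sd, nd


def _codons(seq: str) -> List[str]:
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def _usable_codon_indices(seqs: List[str]) -> List[int]:
    """Codon positions free of gaps/N in every sequence (complete deletion)."""
    ncod = len(seqs[0]) // 3
    keep = []
    for i in range(ncod):
        ok = True
        for s in seqs:
            cod = s[3 * i:3 * i + 3]
            if any(ch not in _BASES for ch in cod):
                ok = False
                break
        if ok:
            keep.append(i)
    return keep


def _pair_proportions(s1: str, s2: str, codon_idx: List[int]) -> Tuple[float, float, float, float]:
    """(Sd, Nd, S_sites, N_sites) between two CDS haplotypes over kept codons."""
    Sd = Nd = Ss = Ns = 0.0
    for i in codon_idx:
        c1, c2 = s1[3 * i:3 * i + 3], s2[3 * i:3 * i + 3]
        if translate_codon(c1) == "*" or translate_codon(c2) == "*":
            continue
        sd, nd = codon_pair_differences(c1, c2)
        s1s, n1s = codon_site_fractions(c1)
        s2s, n2s = codon_site_fractions(c2)
        Sd += sd
        Nd += nd
        Ss += (s1s + s2s) / 2.0
        Ns += (n1s + n2s) / 2.0
    return Sd, Nd, Ss, Ns


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a difference proportion."""
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class CodingStats:
    syn_sites: float
    nonsyn_sites: float
    piA: float
    piS: float
    piA_piS: Optional[float]
    Ka: Optional[float] = None
    Ks: Optional[float] = None
    Ka_Ks: Optional[float] = None
    Ka_raw: Optional[float] = None
    Ks_raw: Optional[float] = None
    internal_stop: bool = False


def syn_nonsyn_stats(cds_aln: HaplotypeAlignment,
                     outgroup_cds: Optional[str] = None) -> CodingStats:
    """Within-sample piA/piS and (optionally) Ka/Ks against an outgroup CDS.

    piA/piS are uncorrected pairwise proportions; Ka/Ks apply the JC
    correction to the NG86 proportions (raw values are kept alongside).
    """
    if cds_aln.L % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    seqs = list(cds_aln.seqs)
    counts = list(cds_aln.counts)
    all_seqs = seqs + ([outgroup_cds] if outgroup_cds else [])
    codon_idx = _usable_codon_indices(all_seqs)
    from .popdata import consensus_sequence
    cons = consensus_sequence(cds_aln)
    last_codon = cds_aln.L // 3 - 1
    internal_stop = any(translate_codon(cons[3 * i:3 * i + 3]) == "*"
                        for i in codon_idx if i < last_codon)
    # average site counts across sample
    Ss_tot = Ns_tot = 0.0
    wsum = sum(counts)
    for s, c in zip(seqs, counts):
        ss = ns = 0.0
        for i in codon_idx:
            cod = s[3 * i:3 * i + 3]
            if translate_codon(cod) == "*":
                continue
            a, b = codon_site_fractions(cod)
            ss += a
            ns += b
        Ss_tot += c * ss
        Ns_tot += c * ns
    Ss_mean, Ns_mean = Ss_tot / wsum, Ns_tot / wsum

    # within-sample pairwise proportions, multiplicity-weighted
    num_pairs = 0.0
    pA_sum = pS_sum = 0.0
    for (i, (s1, c1)), (j, (s2, c2)) in itertools.combinations(
            enumerate(zip(seqs, counts)), 2):
        Sd, Nd, Ss, Ns = _pair_proportions(s1, s2, codon_idx)
        w = c1 * c2
        if Ss > 0:
            pS_sum += w * Sd / Ss
        if Ns > 0:
            pA_sum += w * Nd / Ns
        num_pairs += w
    piA = pA_sum / num_pairs if num_pairs else 0.0
    piS = pS_sum / num_pairs if num_pairs else 0.0
    ratio = piA / piS if piS > 0 else None

    Ka = Ks = KaKs = Ka_raw = Ks_raw = None
    if outgroup_cds is not None:
        if len(outgroup_cds) != cds_aln.L:
            raise ValueError("outgroup CDS length mismatch")
        pN_sum = pS2_sum = 0.0
        for s, c in zip(seqs, counts):
            Sd, Nd, Ss, Ns = _pair_proportions(s, outgroup_cds, codon_idx)
            pS2_sum += c * (Sd / Ss if Ss > 0 else 0.0)
            pN_sum += c * (Nd / Ns if Ns > 0 else 0.0)
        Ka_raw = pN_sum / wsum
        Ks_raw = pS2_sum / wsum
        Ka = jc_correct(Ka_raw)
        Ks = jc_correct(Ks_raw)
        KaKs = Ka / Ks if Ks and Ks > 0 and math.isfinite(Ks) else None
    return CodingStats(syn_sites=Ss_mean, nonsyn_sites=Ns_mean,
                       piA=piA, piS=piS, piA_piS=ratio,
                       Ka=Ka, Ks=Ks, Ka_Ks=KaKs, Ka_raw=Ka_raw, Ks_raw=Ks_raw,
                       internal_stop=internal_stop)


@dataclass
class MKTable:
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    fisher_p: float
    neutrality_index: Optional[float]

    @property
    def table(self) -> List[List[int]]:
        return [[self.Dn, self.Ds], [self.Pn, self.Ps]]


def _site_is_nonsyn(cons: str, pos0: int, b1: str, b2: str) -> bool:
    """Does swapping b1->b2 at 0-based CDS position change the amino acid,
    holding the rest of the codon at the consensus?"""
    ci = pos0 // 3
    off = pos0 % 3
    cod = list(cons[3 * ci:3 * ci + 3])
    cod[off] = b1
    aa1 = translate_codon("".join(cod))
    cod[off] = b2
    aa2 = translate_codon("".join(cod))
    return aa1 != aa2


def mcdonald_kreitman(cds_aln: HaplotypeAlignment, outgroup_cds: str) -> MKTable:
    """McDonald-Kreitman 2x2 test on a CDS alignment vs an outgroup CDS."""
    if cds_aln.L % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if len(outgroup_cds) != cds_aln.L:
        raise ValueError("outgroup CDS length mismatch")
    from .popdata import consensus_sequence
    cons = consensus_sequence(cds_aln)
    codon_idx = set(_usable_codon_indices(list(cds_aln.seqs) + [outgroup_cds]))
    sites = call_segregating_sites(cds_aln, maf_threshold=0.0)
    seg_positions = set(sites.positions)
    Pn = Ps = 0
    for r in sites:
        if (r.position - 1) // 3 not in codon_idx:
            continue
        alleles = sorted(r.counts)
        # use the two most frequent alleles at tri-allelic sites
        if len(alleles) > 2:
            alleles = sorted(r.counts, key=lambda a: -r.counts[a])[:2]
        if _site_is_nonsyn(cons, r.position - 1, alleles[0], alleles[1]):
            Pn += 1
        else:
            Ps += 1
    Dn = Ds = 0
    for pos0 in range(cds_aln.L):
        if pos0 // 3 not in codon_idx:
            continue
        if (pos0 + 1) in seg_positions:
            continue
        b_in = cons[pos0]
        b_out = outgroup_cds[pos0]
        if b_in == b_out or b_out not in _BASES or b_in not in _BASES:
            continue
        # monomorphic in-sample check (consensus equals every haplotype here
        # because the position is not segregating)
        if _site_is_nonsyn(cons, pos0, b_in, b_out):
            Dn += 1
        else:
            Ds += 1
    _, p = stats.fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
    ni = None
    if Ps > 0 and Ds > 0 and Dn > 0:
        ni = (Pn / Ps) / (Dn / Ds)
    return MKTable(Dn=Dn, Ds=Ds, Pn=Pn, Ps=Ps, fisher_p=float(p), neutrality_index=ni)
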