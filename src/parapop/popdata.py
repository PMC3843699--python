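"""Data model and I/O for haplotype alignments, site tables, region maps and masking.

The central container is :class:`HaplotypeAlignment`: a set of aligned
haplotype sequences with integer multiplicities, so a sample of ``n``
chromosomes collapsing to ``k`` distinct variants is stored as ``k`` rows.
Coordinates are 1-based within the analysis frame; ``frame_offset`` maps
internal positions to an external coordinate label, and ``positions`` (when
set) records the frame position of every retained column so that
sites-only alignments and column subsets keep their original labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGT")
VALID_SYMBOLS = VALID_BASES | {"-", "N"}


class FormatError(ValueError):
    """Malformed input file or inconsistent alignment."""


@dataclass
class HaplotypeAlignment:
    ids: List[str]
    seqs: List[str]
    counts: List[int]
    frame_offset: int = 0
    #: frame position (1-based) of each column; None means columns 1..L
    positions: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise FormatError("alignment has no sequences")
        L = len(self.seqs[0])
        for s in self.seqs:
            if len(s) != L:
                raise FormatError("sequences have unequal lengths")
            bad = set(s.upper()) - VALID_SYMBOLS
            if bad:
                raise FormatError(f"invalid symbols in sequence: {sorted(bad)}")
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs) or len(self.counts) != len(self.seqs):
            raise FormatError("ids/seqs/counts length mismatch")
        for c in self.counts:
            if int(c) < 1:
                raise FormatError("haplotype multiplicities must be >= 1")
        self.counts = [int(c) for c in self.counts]
        if self.positions is not None and len(self.positions) != L:
            raise FormatError("positions metadata must have one entry per column")

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return sum(self.counts)

    def column_positions(self) -> List[int]:
        return list(self.positions) if self.positions is not None else list(range(1, self.L + 1))

    def column(self, j: int) -> List[Tuple[str, int]]:
        """Symbols with multiplicities at 0-based column j."""
        return [(s[j], c) for s, c in zip(self.seqs, self.counts)]

    def allele_counts(self, j: int) -> Counter:
        ctr: Counter = Counter()
        for sym, c in self.column(j):
            ctr[sym] += c
        return ctr

    def expand(self) -> "HaplotypeAlignment":
        """One row per chromosome (all multiplicities 1)."""
        ids, seqs = [], []
        for i, (hid, s, c) in enumerate(zip(self.ids, self.seqs, self.counts)):
            for rep in range(c):
                ids.append(hid if c == 1 else f"{hid}.{rep+1}")
                seqs.append(s)
        return HaplotypeAlignment(ids, seqs, [1] * len(seqs), self.frame_offset,
                                  None if self.positions is None else list(self.positions))


@dataclass
class Outgroup:
    seq: str
    label: str = "outgroup"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def base_at(self, pos: int) -> str:
        """Base at a 1-based frame position."""
        return self.seq[pos - 1]


@dataclass
class SiteRecord:
    position: int
    counts: Dict[str, int]
    region: Optional[str] = None
    ancestral: Optional[str] = None
    derived_count: Optional[int] = None
    polarizable: Optional[bool] = None

    @property
    def alleles(self) -> List[str]:
        return sorted(self.counts)

    @property
    def minor_count(self) -> int:
        return min(self.counts.values())

    def major_allele(self) -> str:
        return max(sorted(self.counts), key=lambda a: self.counts[a])


class SiteTable:
    """Segregating sites with allele counts; rows sorted by position."""

    def __init__(self, records: Iterable[SiteRecord], n: int):
        recs = sorted(records, key=lambda r: r.position)
        positions = [r.position for r in recs]
        if len(set(positions)) != len(positions):
            raise FormatError("duplicate site positions")
        for r in recs:
            if sum(r.counts.values()) != n:
                raise FormatError(
                    f"allele counts at position {r.position} sum to "
                    f"{sum(r.counts.values())}, expected n={n}")
            if r.derived_count is not None and not (1 <= r.derived_count <= n - 1):
                raise ValueError(f"derived_count out of [1, n-1] at {r.position}")
        self.records: List[SiteRecord] = recs
        self.n = n

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def S(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> List[int]:
        return [r.position for r in self.records]

    def record_at(self, position: int) -> Optional[SiteRecord]:
        for r in self.records:
            if r.position == position:
                return r
        return None

    def in_intervals(self, intervals: Sequence[Tuple[int, int]]) -> "SiteTable":
        keep = [r for r in self.records
                if any(a <= r.position <= b for a, b in intervals)]
        return SiteTable(keep, self.n)

    def drop_intervals(self, intervals: Sequence[Tuple[int, int]]) -> "SiteTable":
        keep = [r for r in self.records
                if not any(a <= r.position <= b for a, b in intervals)]
        return SiteTable(keep, self.n)

    def by_region(self, label: str) -> "SiteTable":
        return SiteTable([r for r in self.records if r.region == label], self.n)

    def with_regions(self, regions: "RegionMap") -> "SiteTable":
        recs = [replace(r, region=regions.label_of(r.position)) for r in self.records]
        return SiteTable(recs, self.n)

    def polarized(self) -> "SiteTable":
        """Only rows usable for the unfolded SFS."""
        return SiteTable([r for r in self.records if r.polarizable], self.n)


class RegionMap:
    """Named, non-overlapping, 1-based closed intervals (a label may repeat)."""

    def __init__(self, intervals: Iterable[Tuple[str, int, int]]):
        ivs = sorted(intervals, key=lambda t: t[1])
        last_end = 0
        for label, a, b in ivs:
            if a < 1 or b < a:
                raise ValueError(f"bad interval {label}: [{a}, {b}]")
            if a <= last_end:
                raise ValueError(f"overlapping intervals at {label} [{a}, {b}]")
            last_end = b
        self.intervals: List[Tuple[str, int, int]] = ivs

    @property
    def labels(self) -> List[str]:
        seen: List[str] = []
        for label, _, _ in self.intervals:
            if label not in seen:
                seen.append(label)
        return seen

    def label_of(self, pos: int) -> str:
        for label, a, b in self.intervals:
            if a <= pos <= b:
                return label
        return "other"

    def intervals_for(self, label: str) -> List[Tuple[int, int]]:
        return [(a, b) for lab, a, b in self.intervals if lab == label]

    def length(self, label: str) -> int:
        return sum(b - a + 1 for a, b in self.intervals_for(label))

    @classmethod
    def read_tsv(cls, path) -> "RegionMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["label", "start", "end"])
        return cls([(str(r.label), int(r.start), int(r.end)) for r in df.itertuples()])

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.intervals, columns=["label", "start", "end"]).to_csv(
            path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta_alignment(path, counts_from_header: bool = False) -> HaplotypeAlignment:
    """Read an aligned FASTA; multiplicity from a ``;count=k`` header suffix."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty FASTA: {path}")
    ids, seqs, counts = [], [], []
    for rec in records:
        name = rec.id
        count = 1
        if counts_from_header and ";count=" in rec.description:
            head, _, tail = rec.description.rpartition(";count=")
            try:
                count = int(tail.strip())
            except ValueError as exc:
                raise FormatError(f"bad count tag in header {rec.description!r}") from exc
            name = head.split()[0] if head.split() else rec.id.split(";")[0]
        ids.append(name)
        seqs.append(str(rec.seq))
        counts.append(count)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    return HaplotypeAlignment(ids, seqs, counts)


def write_fasta_alignment(aln: HaplotypeAlignment, path, counts_in_header: bool = True) -> None:
    recs = []
    for hid, s, c in zip(aln.ids, aln.seqs, aln.counts):
        name = f"{hid};count={c}" if counts_in_header else hid
        recs.append(SeqRecord(Seq(s), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_outgroup(path, label: Optional[str] = None) -> Outgroup:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError("outgroup FASTA must contain exactly one record")
    return Outgroup(str(records[0].seq), label or records[0].id)


# ---------------------------------------------------------------------------
# Site-table TSV I/O (haplotype-by-site layout)

def read_site_table(path) -> Tuple[HaplotypeAlignment, SiteTable]:
    """Read a haplotype-by-site TSV: header ``pos<TAB>p1...``, rows ``hapID<TAB>count<TAB>alleles``.

    Returns a sites-only alignment (columns carry frame positions) plus the
    corresponding :class:`SiteTable`. Monomorphic columns are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or df.columns[0] != "pos":
        raise FormatError("site table must start with 'pos' and 'count' columns")
    pos_cols = list(df.columns[2:])
    positions = []
    for c in pos_cols:
        try:
            positions.append(int(c))
        except ValueError as exc:
            raise FormatError(f"non-integer site position header {c!r}") from exc
    if len(set(positions)) != len(positions):
        raise FormatError("duplicate site positions in header")
    if positions != sorted(positions):
        raise FormatError("site positions must be increasing")
    ids = df.iloc[:, 0].tolist()
    counts = [int(x) for x in df.iloc[:, 1].tolist()]
    seqs = ["".join(str(df.iloc[i][c]).strip().upper() for c in pos_cols)
            for i in range(len(df))]
    for s in seqs:
        bad = set(s) - (VALID_BASES | {"-"})
        if bad:
            raise FormatError(f"invalid allele symbols {sorted(bad)} in site table")
    aln = HaplotypeAlignment(ids, seqs, counts, positions=positions)
    sites = call_segregating_sites(aln, maf_threshold=0.0)
    if sites.S != len(positions):
        mono = sorted(set(positions) - set(sites.positions))
        raise FormatError(f"monomorphic site columns: {mono}")
    return aln, sites


def write_site_table(aln: HaplotypeAlignment, path) -> None:
    positions = aln.column_positions()
    data = {"pos": aln.ids, "count": aln.counts}
    for j, p in enumerate(positions):
        data[str(p)] = [s[j] for s in aln.seqs]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core operations

def collapse_haplotypes(aln: HaplotypeAlignment) -> List[Tuple[str, int]]:
    """Distinct sequences with total multiplicities, by count desc then lexicographic."""
    ctr: Counter = Counter()
    for s, c in zip(aln.seqs, aln.counts):
        ctr[s] += c
    return sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))


def consensus_sequence(aln: HaplotypeAlignment) -> str:
    """Majority base per column (ties broken alphabetically; gaps/N ignored
    unless a column is all gap/N)."""
    out = []
    for j in range(aln.L):
        ctr = aln.allele_counts(j)
        bases = {b: c for b, c in ctr.items() if b in VALID_BASES}
        if not bases:
            out.append("-")
            continue
        best = max(sorted(bases), key=lambda b: bases[b])
        out.append(best)
    return "".join(out)


def call_segregating_sites(aln: HaplotypeAlignment, maf_threshold: float = 0.0,
                           gap_policy: str = "drop_column") -> SiteTable:
    """Polymorphic columns with minor-allele frequency >= threshold.

    ``gap_policy='drop_column'`` (default) excludes any column containing a
    gap or N from consideration; ``'ignore'`` scores only the called bases.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 chromosomes to call segregating sites")
    if not (0 <= maf_threshold < 0.5):
        raise ValueError("maf_threshold must be in [0, 0.5)")
    if gap_policy != "drop_column":
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    positions = aln.column_positions()
    records = []
    for j in range(aln.L):
        ctr = aln.allele_counts(j)
        if ("-" in ctr) or ("N" in ctr):
            continue
        bases = {b: c for b, c in ctr.items() if b in VALID_BASES}
        if len(bases) < 2:
            continue
        if min(bases.values()) / aln.n >= maf_threshold:
            records.append(SiteRecord(position=positions[j], counts=dict(bases)))
    return SiteTable(records, aln.n)


def polarize_sites(sites: SiteTable, outgroup: Outgroup) -> SiteTable:
    """Set ancestral state and derived counts from an aligned outgroup.

    Sites where the outgroup base matches neither observed allele (or is a
    gap/N) are flagged unpolarizable; they stay in the table for folded
    statistics but are excluded from the unfolded SFS.
    """
    out_records = []
    for r in sites:
        og = outgroup.base_at(r.position)
        if og in r.counts and og in VALID_BASES:
            derived = sum(c for b, c in r.counts.items() if b != og)
            out_records.append(replace(r, ancestral=og, derived_count=derived,
                                       polarizable=True))
        else:
            out_records.append(replace(r, ancestral=None, derived_count=None,
                                       polarizable=False))
    return SiteTable(out_records, sites.n)


def subset_columns(aln: HaplotypeAlignment, intervals: Sequence[Tuple[int, int]],
                   mode: str = "keep") -> HaplotypeAlignment:
    """Keep or drop the columns whose frame positions fall in closed intervals."""
    if mode not in ("keep", "drop"):
        raise ValueError(f"mode must be 'keep' or 'drop', got {mode!r}")
    positions = aln.column_positions()
    frame_max = max(positions) if positions else 0
    for a, b in intervals:
        if a < 1 or b < a or b > max(frame_max, aln.frame_offset + frame_max):
            raise ValueError(f"interval [{a}, {b}] outside frame [1, {frame_max}]")
    if mode == "drop" and not intervals:
        return HaplotypeAlignment(list(aln.ids), list(aln.seqs), list(aln.counts),
                                  aln.frame_offset, list(positions))
    inside = [any(a <= p <= b for a, b in intervals) for p in positions]
    keep = inside if mode == "keep" else [not x for x in inside]
    idx = [j for j, k in enumerate(keep) if k]
    if not idx:
        raise ValueError("subset would remove every column")
    seqs = ["".join(s[j] for j in idx) for s in aln.seqs]
    return HaplotypeAlignment(list(aln.ids), seqs, list(aln.counts),
                              aln.frame_offset, [positions[j] for j in idx])
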