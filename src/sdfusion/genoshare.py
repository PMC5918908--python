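"""Deletion genotyping, read-depth copy-number calls and cross-species sharing.

Covers the population side of the analysis: allele frequencies from PCR
genotype counts, copy-number genotypes from the ratio of read depth in the
gene to genome-wide depth, and the comparison of two species' deletion
callsets under a reciprocal-overlap criterion (two deletions "share" a
locus when the intersection covers at least a threshold fraction — default
70% — of *each* interval).

Intervals are 0-based half-open (BED convention); a converter from 1-based
inclusive coordinates is provided for callsets quoted in that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenotypeTable",
    "DepthSummary",
    "DeletionCall",
    "allele_frequency",
    "depth_ratio_call",
    "reciprocal_overlap",
    "shared_deletions",
    "filter_genic_common",
    "read_bed",
    "write_bed",
    "from_one_based_inclusive",
]


@dataclass(frozen=True)
class GenotypeTable:
    """Counts of individuals per deletion genotype in one species."""

    n_hom_del: int
    n_het: int
    n_hom_ref: int
    species: str = ""

    def __post_init__(self) -> None:
        if min(self.n_hom_del, self.n_het, self.n_hom_ref) < 0:
            raise ValueError("genotype counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_hom_del + self.n_het + self.n_hom_ref


@dataclass(frozen=True)
class DepthSummary:
    """Mean read depth over the gene interval and genome-wide."""

    mean_depth_region: float
    mean_depth_genome: float

    def __post_init__(self) -> None:
        if self.mean_depth_genome <= 0:
            raise ValueError("genome-wide depth must be positive")
        if self.mean_depth_region < 0:
            raise ValueError("region depth must be >= 0")


@dataclass(frozen=True)
class DeletionCall:
    """A deletion interval (0-based, half-open) with optional annotations."""

    chrom: str
    start: int
    end: int
    species: str = ""
    id: str = ""
    genic: bool = False
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")
        if self.allele_freq is not None and not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError("allele_freq must be in [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start


def from_one_based_inclusive(chrom: str, start: int, end: int, **kw) -> DeletionCall:
    """Build a call from 1-based inclusive coordinates (e.g. quoted loci)."""
    return DeletionCall(chrom=chrom, start=start - 1, end=end, **kw)


def allele_frequency(g: GenotypeTable) -> tuple[int, int, float]:
    """Deletion allele count, total allele count and frequency.

    Exact arithmetic: n_del = 2*hom_del + het over 2*total alleles. Note
    that published frequencies are sometimes rounded inconsistently with
    their own counts (e.g. 29/74 = 0.392 printed as 0.41); this function
    always reports the exact ratio.
    """
    if g.total == 0:
        raise ValueError("empty genotype table")
    n_del = 2 * g.n_hom_del + g.n_het
    n_alleles = 2 * g.total
    return n_del, n_alleles, n_del / n_alleles


def depth_ratio_call(d: DepthSummary) -> tuple[float, int, str]:
    """Copy number and genotype from the region/genome depth ratio.

    copy_number = round-half-up of 2*ratio; 0 copies -> hom_del, 1 -> het,
    >= 2 -> hom_ref.
    """
    ratio = d.mean_depth_region / d.mean_depth_genome
    copy_number = int(2.0 * ratio + 0.5)  # round half up; ratio >= 0
    call = "hom_del" if copy_number == 0 else "het" if copy_number == 1 else "hom_ref"
    return ratio, copy_number, call


def reciprocal_overlap(
    a: DeletionCall, b: DeletionCall, threshold: float = 0.7
) -> tuple[float, float, bool]:
    """Overlap fractions of each interval and the shared flag.

    ``shared`` requires the intersection to cover at least ``threshold`` of
    *both* intervals (inclusive comparison at the boundary). Different
    chromosomes never share.
    """
    if a.chrom != b.chrom:
        return 0.0, 0.0, False
    o = min(a.end, b.end) - max(a.start, b.start)
    if o <= 0:
        return 0.0, 0.0, False
    fa = o / len(a)
    fb = o / len(b)
    return fa, fb, bool(fa >= threshold and fb >= threshold)


def shared_deletions(
    set_a: Sequence[DeletionCall],
    set_b: Sequence[DeletionCall],
    threshold: float = 0.7,
) -> tuple[list[tuple[str, str]], dict]:
    """All cross-set pairs passing reciprocal overlap, via an interval index.

    Returns (pairs, summary): pairs of (a_id, b_id) — a call may match
    several partners and every passing pair is reported — and a summary
    with the number and fraction of set_a calls having at least one
    partner. Pair order follows set_a order, then set_b order.
    """
    by_chrom: dict[str, IntervalTree] = {}
    b_order = {id(b): k for k, b in enumerate(set_b)}
    for b in set_b:
        by_chrom.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)

    pairs: list[tuple[str, str]] = []
    a_with_partner = 0
    for i, a in enumerate(set_a):
        tree = by_chrom.get(a.chrom)
        if tree is None:
            continue
        hits = []
        for iv in tree.overlap(a.start, a.end):
            b = iv.data
            _, _, shared = reciprocal_overlap(a, b, threshold)
            if shared:
                hits.append(b)
        if hits:
            a_with_partner += 1
            hits.sort(key=lambda b: b_order[id(b)])
            pairs.extend((a.id or f"a{i}", b.id or f"b{b_order[id(b)]}") for b in hits)

    summary = {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_pairs": len(pairs),
        "n_a_shared": a_with_partner,
        "frac_a_shared": a_with_partner / len(set_a) if set_a else 0.0,
        "threshold": threshold,
    }
    return pairs, summary


def filter_genic_common(
    calls: Sequence[DeletionCall],
    genes: Sequence[tuple[str, int, int]],
    min_freq: float,
) -> list[DeletionCall]:
    """Subset to calls overlapping any gene (any overlap) with allele_freq >= min_freq.

    Calls lacking an allele frequency are excluded with a warning.
    """
    gene_trees: dict[str, IntervalTree] = {}
    for chrom, start, end in genes:
        gene_trees.setdefault(chrom, IntervalTree()).addi(start, end)

    out: list[DeletionCall] = []
    for c in calls:
        tree = gene_trees.get(c.chrom)
        if tree is None or not tree.overlap(c.start, c.end):
            continue
        if c.allele_freq is None:
            warnings.warn(f"call {c.id or c} has no allele frequency; excluded", stacklevel=2)
            continue
        if c.allele_freq >= min_freq:
            out.append(c)
    return out


# ---- BED I/O --------------------------------------------------------------


def read_bed(path: str | Path, species: str = "") -> list[DeletionCall]:
    """Read a BED(-like) callset: chrom, start, end[, id[, allele_freq]].

    Malformed lines are reported with their line number.
    """
    calls: list[DeletionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                call_id = parts[3] if len(parts) > 3 and parts[3] != "." else ""
                freq = None
                if len(parts) > 4 and parts[4] not in (".", ""):
                    freq = float(parts[4])
                calls.append(
                    DeletionCall(chrom=chrom, start=start, end=end, species=species,
                                 id=call_id, allele_freq=freq)
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}") from exc
    return calls


def write_bed(calls: Iterable[DeletionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            freq = "." if c.allele_freq is None else f"{c.allele_freq:g}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id or '.'}\t{freq}\n")
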