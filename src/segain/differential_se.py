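"""Gained/lost/shared classification of SE calls and cross-line intersection.

"Gain" is presence/absence by overlap: a treated super-enhancer with zero
bp of overlap against every parental super-enhancer is gained (and
symmetrically, a parental SE untouched by any treated SE is lost). No
fold-change threshold is applied by default — the comparison the method
reports is a discrete peak-set difference — but a minimum treated/parental
signal ratio can be requested via ``min_fold``.

Gains from two cell lines are grouped by transitive >= 1 bp overlap; each
connected group becomes one merged common-gain region whose interval is
the union hull of its contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .genomic_io import GenomicInterval
from .se_calling import SECallResult, StitchedRegion

__all__ = [
    "DifferentialSE",
    "MergedGainRegion",
    "classify_gain_loss",
    "intersect_gains",
    "write_merged_regions",
]


@dataclass
class DifferentialSE:
    region: StitchedRegion
    status: str  # gained | lost | shared
    partner_overlap_bp: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("gained", "lost", "shared"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in ("gained", "lost") and self.partner_overlap_bp != 0:
            raise ValueError("gained/lost regions must have zero partner overlap")


@dataclass
class MergedGainRegion:
    merged_region_id: int
    interval: GenomicInterval
    contributing: Dict[str, List[GenomicInterval]]
    annotations: list = field(default_factory=list)


def _chrom_namespace(result: SECallResult) -> set:
    return {r.interval.chrom.startswith("chr") for r in result.regions}


def classify_gain_loss(
    treated: SECallResult,
    parental: SECallResult,
    min_fold: Optional[float] = None,
) -> list:
    """Classify treated SEs as gained/shared and parental SEs as lost.

    Returns one entry per treated SE (gained or shared, on treated
    coordinates) plus one per lost parental SE (on parental coordinates).
    With ``min_fold``, a gained call additionally requires
    treated tag_count >= min_fold * (max overlapping-parental-region
    tag count, over ALL parental stitched regions) — off by default.
    """
    if _chrom_namespace(treated) != _chrom_namespace(parental) and treated.regions \
            and parental.regions:
        raise ValueError("treated/parental chromosome namespaces do not match")
    parental_se = parental.super_enhancers
    treated_se = treated.super_enhancers
    out = []
    for r in treated_se:
        ov = sum(r.interval.overlap_bp(p.interval) for p in parental_se)
        if ov > 0:
            out.append(DifferentialSE(r, "shared", partner_overlap_bp=ov))
            continue
        if min_fold is not None:
            base = max(
                (p.tag_count for p in parental.regions
                 if p.interval.overlaps(r.interval)),
                default=0.0,
            )
            if base > 0 and r.tag_count < min_fold * base:
                out.append(DifferentialSE(r, "shared", partner_overlap_bp=0))
                continue
        out.append(DifferentialSE(r, "gained"))
    for p in parental_se:
        ov = sum(p.interval.overlap_bp(r.interval) for r in treated_se)
        if ov == 0:
            out.append(DifferentialSE(p, "lost"))
    return out


def intersect_gains(
    gains_a: Sequence[DifferentialSE],
    gains_b: Sequence[DifferentialSE],
    line_names: tuple = ("A", "B"),
) -> list:
    """Group cross-line overlapping gains into merged common-gain regions.

    Connected components of the transitive >= 1 bp overlap relation over
    the combined gain set; only components containing at least one gain
    from EACH line are reported. Hull = union span; ids assigned in
    (chrom, start) order starting at 1. Symmetric in its arguments.
    """
    for g in list(gains_a) + list(gains_b):
        if g.status != "gained":
            raise ValueError("intersect_gains expects gained-status entries only")
    items = [(line_names[0], g.region.interval) for g in gains_a] + [
        (line_names[1], g.region.interval) for g in gains_b
    ]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # single-linkage by sweeping start-sorted intervals per chromosome
    order = sorted(range(n), key=lambda i: (items[i][1].chrom, items[i][1].start))
    active: List[int] = []
    for i in order:
        iv = items[i][1]
        active = [j for j in active if items[j][1].chrom == iv.chrom
                  and items[j][1].end > iv.start]
        for j in active:
            union(i, j)
        active.append(i)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for members in groups.values():
        lines = {items[i][0] for i in members}
        if set(line_names) - lines:
            continue
        ivs = [items[i][1] for i in members]
        hull = GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )
        contributing: Dict[str, List[GenomicInterval]] = {ln: [] for ln in line_names}
        for i in members:
            contributing[items[i][0]].append(items[i][1])
        for ln in line_names:
            contributing[ln].sort()
        merged.append((hull, contributing))
    merged.sort(key=lambda m: (m[0].chrom, m[0].start))
    return [
        MergedGainRegion(merged_region_id=k + 1, interval=hull,
                         contributing=contributing)
        for k, (hull, contributing) in enumerate(merged)
    ]


def write_merged_regions(regions: Sequence[MergedGainRegion], path) -> None:
    """TSV mirroring the published common-gain table's region columns."""
    with open(path, "w") as fh:
        fh.write("MergedRegion\tChromosome\tStart\tEnd\tLength\n")
        for r in regions:
            fh.write(
                f"{r.merged_region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{r.interval.length()}\n"
            )
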