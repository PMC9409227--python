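"""ROSE-style super-enhancer calling: blacklist, stitch, rank, top 5%.

Peaks on a chromosome are stitched whenever the gap between consecutive
start-sorted peaks (next.start - prev.end) is strictly less than the
stitching distance (default 12,500 bp, so a 12,500-bp gap is NOT merged).
Stitched regions are quantified as reads-per-million of the sample's own
coverage track, ranked by tag count, and the top 5% (floor, minimum one)
are designated super-enhancers.

Tie-break for ranking is total and deterministic: tag count descending,
then region length descending, then (chrom, start) ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

from .coverage import CoverageTrack
from .genomic_io import GenomicInterval, Peak

__all__ = [
    "SECallParams",
    "StitchedRegion",
    "SECallResult",
    "filter_blacklist",
    "stitch_peaks",
    "quantify_regions",
    "call_superenhancers",
    "write_se_table",
    "read_se_bed",
]


@dataclass(frozen=True)
class SECallParams:
    stitch_distance: int = 12_500  # strict less-than rule
    top_fraction: float = 0.05
    blacklist: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class StitchedRegion:
    """A candidate super-enhancer: the hull of a chain of stitched peaks."""

    interval: GenomicInterval
    member_peaks: List[Peak]
    tag_count: float = 0.0
    rank: int = 0
    is_super: bool = False


@dataclass
class SECallResult:
    regions: List[StitchedRegion]  # in rank order
    se_count: int
    params: SECallParams

    @property
    def super_enhancers(self) -> List[StitchedRegion]:
        return [r for r in self.regions if r.is_super]


def filter_blacklist(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list:
    """Drop peaks overlapping any blacklist interval by >= 1 bp; keep order."""
    if not blacklist:
        return list(peaks)
    by_chrom: dict = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = []
    for p in peaks:
        hits = by_chrom.get(p.interval.chrom, ())
        if not any(p.interval.overlaps(b) for b in hits):
            out.append(p)
    return out


def stitch_peaks(
    peaks: Sequence[Peak], params: SECallParams = SECallParams()
) -> list:
    """Single-linkage chain peaks per chromosome at gap < stitch_distance.

    Overlapping or abutting peaks (gap <= 0) always merge. Every input
    peak lands in exactly one region; region hulls are pairwise disjoint
    per chromosome. Output is sorted by (chrom, start).
    """
    by_chrom: dict = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    regions = []
    for chrom in sorted(by_chrom):
        chain = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        members: List[Peak] = []
        hull_end = None
        hull_start = None
        for p in chain:
            if members and p.interval.start - hull_end < params.stitch_distance:
                members.append(p)
                hull_end = max(hull_end, p.interval.end)
            else:
                if members:
                    regions.append(
                        StitchedRegion(
                            GenomicInterval(chrom, hull_start, hull_end), members
                        )
                    )
                members = [p]
                hull_start, hull_end = p.interval.start, p.interval.end
        if members:
            regions.append(
                StitchedRegion(GenomicInterval(chrom, hull_start, hull_end), members)
            )
    return regions


def quantify_regions(
    regions: Sequence[StitchedRegion], track: CoverageTrack
) -> list:
    """Assign reads-per-million-scaled tag mass to each stitched region.

    tag_count = (track mass overlapping the region) * 1e6 / total track
    mass; partial bin overlap is prorated linearly. Raises on a zero-mass
    track (normalisation undefined).
    """
    total = track.total_mass()
    if total <= 0:
        raise ValueError("cannot normalise against a zero-mass coverage track")
    out = []
    for r in regions:
        mass = track.region_mass(r.interval)
        out.append(replace_tag(r, mass * 1e6 / total))
    return out


def replace_tag(region: StitchedRegion, tag: float) -> StitchedRegion:
    return StitchedRegion(
        interval=region.interval,
        member_peaks=region.member_peaks,
        tag_count=tag,
        rank=region.rank,
        is_super=region.is_super,
    )


def _rank_key(r: StitchedRegion):
    return (-r.tag_count, -r.interval.length(), r.interval.chrom, r.interval.start)


def call_superenhancers(
    regions: Sequence[StitchedRegion], params: SECallParams = SECallParams()
) -> SECallResult:
    """Rank quantified regions and flag the top fraction as super-enhancers.

    se_count = max(1, floor(top_fraction * N)).
    """
    if not regions:
        raise ValueError("no stitched regions to rank")
    ranked = sorted(regions, key=_rank_key)
    se_count = max(1, int(params.top_fraction * len(ranked)))
    out = []
    for i, r in enumerate(ranked):
        out.append(
            StitchedRegion(
                interval=r.interval,
                member_peaks=r.member_peaks,
                tag_count=r.tag_count,
                rank=i + 1,
                is_super=i < se_count,
            )
        )
    return SECallResult(regions=out, se_count=se_count, params=params)


def write_se_table(result: SECallResult, path) -> None:
    """Full ranked table as TSV: chrom, start, end, rank, tag_count, is_super, n_peaks."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\trank\ttag_count\tis_super\tn_peaks\n")
        for r in result.regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.rank}\t{r.tag_count:.6f}\t{int(r.is_super)}\t"
                f"{len(r.member_peaks)}\n"
            )


def read_se_bed(path) -> list:
    """Read a written SE table back as StitchedRegions (peaks not recovered)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                StitchedRegion(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    member_peaks=[],
                    tag_count=float(f[idx["tag_count"]]),
                    rank=int(f[idx["rank"]]),
                    is_super=bool(int(f[idx["is_super"]])),
                )
            )
    return out
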