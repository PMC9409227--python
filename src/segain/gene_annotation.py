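"""Gene assignment for merged gain regions: in gene / upstream / downstream.

A gene overlapping the region by >= 1 bp is "in gene". Otherwise the
relation is read strand-aware, region-relative-to-gene: a region lying
entirely on the TSS side of a non-overlapping gene is "upstream" of it,
a region on the 3' side is "downstream". Genes farther than ``window``
(default 50 kb, the conventional enhancer-target assignment span) from
the region edge are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .differential_se import MergedGainRegion
from .genomic_io import GeneModel

__all__ = ["AnnotationParams", "GeneAnnotation", "annotate_region", "annotate_all",
           "write_annotated"]

_PRIORITY = {"in gene": 0, "upstream": 1, "downstream": 2}


@dataclass(frozen=True)
class AnnotationParams:
    window: int = 50_000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass(frozen=True)
class GeneAnnotation:
    gene: GeneModel
    relation: str  # in gene | upstream | downstream
    distance: int  # bp edge-to-edge; 0 when overlapping


def annotate_region(
    region: MergedGainRegion,
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
) -> List[GeneAnnotation]:
    """All genes within ``window`` of the region, sorted by relation then distance."""
    iv = region.interval
    out = []
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        if iv.overlaps(g.interval):
            out.append(GeneAnnotation(g, "in gene", 0))
            continue
        dist = iv.distance_to(g.interval)
        if dist > params.window:
            continue
        region_is_left = iv.end <= g.interval.start
        # on the TSS side: left of a + gene, or right of a - gene
        if region_is_left == (g.strand == "+"):
            relation = "upstream"
        else:
            relation = "downstream"
        out.append(GeneAnnotation(g, relation, dist))
    out.sort(key=lambda a: (_PRIORITY[a.relation], a.distance, a.gene.symbol))
    return out


def annotate_all(
    regions: Sequence[MergedGainRegion],
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
) -> List[MergedGainRegion]:
    """Attach annotations to every region (empty list when nothing in window)."""
    for r in regions:
        r.annotations = annotate_region(r, genes, params)
    return list(regions)


def write_annotated(regions: Sequence[MergedGainRegion], path) -> None:
    """TSV with the published table's final columns (gene list + positions)."""
    with open(path, "w") as fh:
        fh.write("MergedRegion\tChromosome\tStart\tEnd\tLength\tGeneList\tPosition\n")
        for r in regions:
            genes = ";".join(a.gene.symbol for a in r.annotations)
            pos = ";".join(a.relation for a in r.annotations)
            fh.write(
                f"{r.merged_region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{r.interval.length()}\t{genes}\t{pos}\n"
            )
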