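"""Genomic interval types and flat-file I/O.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package, matching BED/narrowPeak semantics. The packaged 68-region
reference table (common gained super-enhancer loci with their annotated
genes) uses the same convention: for every printed row, ``end - start``
equals the printed length, so coordinates are ingested verbatim.

Chromosome names are canonicalised to the "chr"-prefixed form; bare names
("1", "X") are accepted and normalised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "Fragment",
    "Table1Region",
    "normalize_chrom",
    "read_narrowpeak",
    "read_fragments",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_chrom_sizes",
    "load_table1_fixture",
    "ParseError",
]

MISSING_MAPQ = -1  # sentinel for fragment records without a MAPQ column


class ParseError(ValueError):
    """Raised when a genomic flat file cannot be parsed."""


def normalize_chrom(name: str) -> str:
    """Map bare chromosome names to the canonical chr-prefixed form."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval: {self.chrom}:[{self.start},{self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open abutment is not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Min edge-to-edge gap in bp; 0 if overlapping or abutting."""
        if self.chrom != other.chrom:
            raise ValueError("distance between different chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class Peak:
    """A called peak (e.g. one MACS narrowPeak record)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative peak score: {self.score}")


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; TSS is ``start`` on + and ``end`` on -."""

    symbol: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.symbol}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end


@dataclass(frozen=True)
class Fragment:
    """An aligned sequencing fragment (pre-extension)."""

    interval: GenomicInterval
    strand: str
    mapq: int = MISSING_MAPQ

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"fragment without valid strand: {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end


VALID_POSITIONS = ("in gene", "upstream", "downstream")


@dataclass(frozen=True)
class Table1Region:
    """One row of the packaged common-gain region table (68 rows)."""

    region_no: int
    merged_region_id: int
    interval: GenomicInterval
    printed_length: int
    gene_entries: tuple  # of (symbol, position-label) pairs; symbol may be ""
    upregulated: tuple = ()  # parallel bools: flagged upregulated in the cohort

    def __post_init__(self) -> None:
        if self.printed_length != self.interval.length():
            raise ValueError(
                f"region {self.region_no}: printed length {self.printed_length} "
                f"!= end-start {self.interval.length()}"
            )
        for sym, pos in self.gene_entries:
            if pos not in VALID_POSITIONS:
                raise ValueError(
                    f"region {self.region_no}: unknown position label {pos!r}"
                )

    def gene_symbols(self, drop_noncoding: bool = False) -> list:
        """Gene symbols as printed (empty placeholders removed).

        With ``drop_noncoding=True``, LOC*/MIR*/RNA5S*/LINC* entries are
        also removed — a convenience view, not a claim about the source
        table's own counting rule.
        """
        out = []
        for sym, _pos in self.gene_entries:
            if not sym:
                continue
            if drop_noncoding and any(
                sym.startswith(p) for p in ("LOC", "MIR", "RNA5S", "LINC")
            ):
                continue
            out.append(sym)
        return out


def primary_symbol(symbol: str) -> str:
    """Strip a parenthesised alias: ``C2orf18(SLC35F6)`` -> ``C2orf18``."""
    return symbol.split("(", 1)[0]


# ---------------------------------------------------------------------------
# parsers


def _lines(path) -> Iterable:
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield i, line


def read_narrowpeak(path) -> list:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED peak file."""
    peaks = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
        name = fields[3] if len(fields) > 3 else "."
        try:
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
        summit = None
        if len(fields) >= 10:
            try:
                s = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad summit {fields[9]!r}") from exc
            summit = s if s >= 0 else None
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), name=name, score=score,
                 summit_offset=summit)
        )
    return peaks


def read_fragments(path) -> list:
    """Read aligned fragments from BED6-like input.

    The score column, when present and integer, is taken as MAPQ; a missing
    or "." score yields the missing-MAPQ sentinel. No filtering happens
    here — MAPQ/duplicate filtering is the coverage module's concern.
    """
    frags = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(
                f"{path}:{lineno}: fragment records need 6 columns (strand required)"
            )
        try:
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if start < 0:
            raise ParseError(f"{path}:{lineno}: negative coordinate")
        mapq = MISSING_MAPQ
        if fields[4] not in (".", ""):
            try:
                mapq = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad MAPQ {fields[4]!r}") from exc
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        frags.append(Fragment(iv, strand, mapq))
    return frags


def read_bed(path) -> list:
    """Read a BED3+ file as plain intervals."""
    out = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        try:
            out.append(
                GenomicInterval(normalize_chrom(fields[0]), int(fields[1]),
                                int(fields[2]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(regions: Sequence, path, names: Optional[Sequence] = None) -> None:
    """Write intervals (or objects with ``.interval``) as BED3/BED4."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            iv = r.interval if hasattr(r, "interval") else r
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(str(names[i]))
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path) -> list:
    """Read a gene table TSV: symbol, chrom, start, end, strand (header optional)."""
    genes = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if fields[0] == "symbol":
            continue
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: gene rows need 5 columns")
        symbol, chrom, start, end, strand = fields[:5]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        try:
            iv = GenomicInterval(normalize_chrom(chrom), int(start), int(end))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneModel(symbol, iv, strand))
    return genes


def write_gene_table(genes: Sequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.symbol}\t{g.interval.chrom}\t{g.interval.start}\t"
                f"{g.interval.end}\t{g.strand}\n"
            )


def read_chrom_sizes(path) -> dict:
    """Read a two-column chrom<TAB>size file."""
    sizes = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected chrom<TAB>size")
        sizes[normalize_chrom(fields[0])] = int(fields[1])
    return sizes


def load_table1_fixture() -> list:
    """Load the packaged 68-region common-gain table.

    Returns rows in printed order; every row is validated (end - start must
    equal the printed length, position vocabulary must be known) and a
    corrupted fixture raises naming the offending region number.
    """
    ref = resources.files("segain").joinpath("data/table1_regions.tsv")
    with ref.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        regions = []
        for row in reader:
            region_no = int(row["region_no"])
            genes = row["genes"].split(";")
            positions = row["positions"].split(";")
            upreg = [bool(int(x)) for x in row["upregulated"].split(";")]
            if not (len(genes) == len(positions) == len(upreg)):
                raise ValueError(
                    f"region {region_no}: gene/position/flag arity mismatch"
                )
            try:
                regions.append(
                    Table1Region(
                        region_no=region_no,
                        merged_region_id=int(row["merged_region"]),
                        interval=GenomicInterval(
                            normalize_chrom(row["chromosome"]),
                            int(row["start"]),
                            int(row["end"]),
                        ),
                        printed_length=int(row["length"]),
                        gene_entries=tuple(zip(genes, positions)),
                        upregulated=tuple(upreg),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"fixture region {region_no}: {exc}") from exc
    return regions
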