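"""Synthetic inputs with planted truth for the whole pipeline.

The generator emulates the study design end-to-end on a small genome:

* two "cell lines" (A, B), each with a parental and a treated condition;
* clustered high-density member-peak windows forming planted
  super-enhancers: per line, a set of baseline SEs present in both
  conditions, plus gain SEs present only in the treated condition, a
  subset of which is shared (identical coordinates) between the lines;
* a negative-control locus per line whose member windows sit more than
  12.5 kb apart, so stitching must NOT join them;
* uniform background fragments plus moderately enriched background peak
  windows, giving the top-5% rule a realistic census of stitched regions;
* a tumor/normal expression cohort (log2-normal noise) in which planted
  genes — genes lying nearest the shared-gain loci — carry a tumor
  log2-effect and a high-vs-low-expression hazard ratio on exponential
  survival times with independent censoring.

Within a line, background, background-peak and baseline/negative-control
fragments are drawn from per-component seeded substreams, so the parental
and treated conditions share their background realization and differ
exactly by the planted gain signal (a stable enhancer landscape). All
output is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import Fragment, GeneModel, GenomicInterval, Peak

__all__ = [
    "SyntheticConfig",
    "make_genome_and_genes",
    "plan_loci",
    "simulate_chip",
    "simulate_cohort",
    "choose_planted_genes",
    "write_simulation",
]

LINES = ("A", "B")
CONDITIONS = ("parental", "treated")


@dataclass(frozen=True)
class SyntheticConfig:
    genome: tuple = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_background_peaks: int = 300
    n_planted_se: int = 12  # per treated condition (baseline + gains)
    shared_gain: int = 5  # gains with identical coordinates in both lines
    line_specific_gain: int = 1
    se_peak_count: tuple = (5, 8)  # member windows per planted SE (inclusive)
    se_gap: tuple = (1_000, 11_000)  # bp between member windows (< 12.5 kb)
    neg_gap: tuple = (13_000, 16_000)  # negative control: always > 12.5 kb
    peak_width: int = 1_000
    enrichment: float = 10.0  # planted windows, fold over background density
    background_peak_enrichment: float = 3.0
    n_fragments: int = 200_000  # exact budget per line x condition
    fragment_length: int = 75
    low_mapq_fraction: float = 0.02
    n_genes: Optional[int] = None  # None: tile the genome
    n_tumor: int = 300
    n_normal: int = 30
    planted_genes: int = 4
    log2_effect: float = 1.0
    hazard_ratio: float = 2.0
    noise_sd: float = 0.5
    baseline_median_days: float = 2_500.0
    censor_range: tuple = (200.0, 3_650.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must be > 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.shared_gain + self.line_specific_gain > self.n_planted_se:
            raise ValueError("gains cannot exceed n_planted_se")
        for f in ("n_background_peaks", "n_planted_se", "n_fragments",
                  "n_tumor", "n_normal", "planted_genes"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def n_baseline(self) -> int:
        return self.n_planted_se - self.shared_gain - self.line_specific_gain


def _rng(cfg: SyntheticConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *tags])


# ---------------------------------------------------------------------------
# genome + genes


def make_genome_and_genes(cfg: SyntheticConfig) -> Tuple[dict, List[GeneModel]]:
    """Tile non-overlapping 5-50 kb genes with random gaps on both strands."""
    rng = _rng(cfg, 1)
    sizes = {c: int(l) for c, l in cfg.genome}
    genes: List[GeneModel] = []
    i = 0
    for chrom, length in cfg.genome:
        pos = int(rng.integers(1_000, 10_000))
        while True:
            glen = int(rng.integers(5_000, 50_001))
            if pos + glen > length - 1_000:
                break
            if cfg.n_genes is not None and len(genes) >= cfg.n_genes:
                break
            i += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"G{i:04d}", GenomicInterval(chrom, pos, pos + glen),
                          strand)
            )
            pos += glen + int(rng.integers(2_000, 20_001))
    if cfg.n_genes is not None and len(genes) < cfg.n_genes:
        raise ValueError(
            f"genome too small for {cfg.n_genes} genes (placed {len(genes)})"
        )
    return sizes, genes


# ---------------------------------------------------------------------------
# locus planning

SLOT_SPAN = 150_000
SLOT_GAP = 50_000


@dataclass(frozen=True)
class PlantedLocus:
    locus_id: str
    kind: str  # baseline | shared_gain | line_gain | negative_control
    line: Optional[str]  # None for shared loci
    windows: tuple  # member-window GenomicIntervals

    @property
    def hull(self) -> GenomicInterval:
        return GenomicInterval(
            self.windows[0].chrom,
            min(w.start for w in self.windows),
            max(w.end for w in self.windows),
        )

    @property
    def shared(self) -> bool:
        return self.kind == "shared_gain"


def _slot_starts(cfg: SyntheticConfig, n_slots: int, rng) -> List[Tuple[str, int]]:
    """Non-overlapping slot origins, spread over chromosomes, seeded."""
    chroms = list(cfg.genome)
    pitch = SLOT_SPAN + SLOT_GAP
    capacity = [(c, max(0, (l - SLOT_GAP) // pitch)) for c, l in chroms]
    total = sum(k for _c, k in capacity)
    if n_slots > total:
        raise ValueError(f"genome too small for {n_slots} planted loci")
    grid = [(c, SLOT_GAP + j * pitch) for c, k in capacity for j in range(k)]
    idx = rng.choice(len(grid), size=n_slots, replace=False)
    return [grid[i] for i in sorted(idx)]


def _make_windows(chrom, start, n, gaps, width, rng) -> tuple:
    lo, hi = gaps
    out = []
    pos = start + int(rng.integers(0, 5_000))
    for _ in range(n):
        out.append(GenomicInterval(chrom, pos, pos + width))
        pos += width + int(rng.integers(lo, hi))
    return tuple(out)


def plan_loci(cfg: SyntheticConfig) -> List[PlantedLocus]:
    """Deterministic layout of every planted locus for both lines.

    Shared-gain loci have identical coordinates in both lines; baseline,
    line-specific-gain and negative-control loci are per line.
    """
    rng = _rng(cfg, 2)
    n_slots = (cfg.shared_gain
               + len(LINES) * (cfg.n_baseline + cfg.line_specific_gain + 1))
    slots = _slot_starts(cfg, n_slots, rng)
    loci: List[PlantedLocus] = []
    it = iter(slots)

    def n_windows():
        return int(rng.integers(cfg.se_peak_count[0], cfg.se_peak_count[1] + 1))

    for k in range(cfg.shared_gain):
        c, s = next(it)
        loci.append(PlantedLocus(
            f"shared_gain_{k + 1}", "shared_gain", None,
            _make_windows(c, s, n_windows(), cfg.se_gap, cfg.peak_width, rng)))
    for line in LINES:
        for k in range(cfg.n_baseline):
            c, s = next(it)
            loci.append(PlantedLocus(
                f"{line}_baseline_{k + 1}", "baseline", line,
                _make_windows(c, s, n_windows(), cfg.se_gap, cfg.peak_width, rng)))
        for k in range(cfg.line_specific_gain):
            c, s = next(it)
            loci.append(PlantedLocus(
                f"{line}_gain_{k + 1}", "line_gain", line,
                _make_windows(c, s, n_windows(), cfg.se_gap, cfg.peak_width, rng)))
        c, s = next(it)
        loci.append(PlantedLocus(
            f"{line}_negctrl", "negative_control", line,
            _make_windows(c, s, n_windows(), cfg.neg_gap, cfg.peak_width, rng)))
    return loci


def _loci_for(cfg, loci, line, condition) -> List[PlantedLocus]:
    out = []
    for l in loci:
        if l.line not in (None, line):
            continue
        if l.kind in ("shared_gain", "line_gain") and condition != "treated":
            continue
        out.append(l)
    return out


def truth_table(cfg: SyntheticConfig,
                loci: Optional[List[PlantedLocus]] = None) -> pd.DataFrame:
    """Planted-locus truth for every line x condition."""
    if loci is None:
        loci = plan_loci(cfg)
    rows = []
    for line in LINES:
        for cond in CONDITIONS:
            for l in _loci_for(cfg, loci, line, cond):
                hull = l.hull
                rows.append({
                    "line": line, "condition": cond, "locus_id": l.locus_id,
                    "kind": l.kind, "chrom": hull.chrom, "start": hull.start,
                    "end": hull.end, "shared": l.shared,
                    "n_windows": len(l.windows),
                    "is_gain": l.kind in ("shared_gain", "line_gain"),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# background peaks + fragments


def _background_peaks(cfg: SyntheticConfig, line: str,
                      loci: List[PlantedLocus]) -> List[GenomicInterval]:
    """n background peak windows, >= 13 kb apart and clear of planted slots.

    Placement uses the compressed-coordinate trick per free segment so the
    count is exact and the stitched-region census stays stable (background
    peaks never stitch with each other or bridge into planted loci).
    """
    rng = _rng(cfg, 3, LINES.index(line))
    margin = 13_000
    w = cfg.peak_width
    pitch = w + margin
    blocked: Dict[str, List[Tuple[int, int]]] = {c: [] for c, _l in cfg.genome}
    for l in loci:
        if l.line in (None, line):
            h = l.hull
            blocked[h.chrom].append((h.start - margin, h.end + margin))
    segments = []
    for chrom, length in cfg.genome:
        spans = sorted(blocked[chrom])
        pos = 0
        for s, e in spans:
            if s > pos:
                segments.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            segments.append((chrom, pos, length))
    caps = [max(0, (e - s) // pitch) for _c, s, e in segments]
    total = sum(caps)
    if cfg.n_background_peaks > total:
        raise ValueError("genome too small for requested background peaks")
    counts = (rng.multivariate_hypergeometric(caps, cfg.n_background_peaks)
              if total else [])
    peaks = []
    for (chrom, s, e), k in zip(segments, counts):
        if k == 0:
            continue
        free = (e - s) - k * pitch
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        for j, off in enumerate(offsets):
            start = s + int(off) + j * pitch
            peaks.append(GenomicInterval(chrom, start, start + w))
    peaks.sort()
    return peaks


def _sample_fragments(rng, windows: Sequence[GenomicInterval], k: int,
                      frag_len: int, cfg: SyntheticConfig) -> List[Fragment]:
    """k fragments with 5' starts uniform over the given windows."""
    if k <= 0 or not windows:
        return []
    lens = np.array([w.length() for w in windows], dtype=float)
    choice = rng.choice(len(windows), size=k, p=lens / lens.sum())
    offsets = rng.random(k)
    strands = rng.random(k) < 0.5
    mapqs = np.where(rng.random(k) < cfg.low_mapq_fraction, 10, 60)
    out = []
    for i in range(k):
        w = windows[choice[i]]
        s = w.start + int(offsets[i] * w.length())
        out.append(Fragment(GenomicInterval(w.chrom, s, s + frag_len),
                            "+" if strands[i] else "-", int(mapqs[i])))
    return out


def _allocate(weights: Dict[str, float], total: int) -> Dict[str, int]:
    """Largest-remainder apportionment to an exact total."""
    wsum = sum(weights.values())
    raw = {k: total * v / wsum for k, v in weights.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_chip(
    cfg: SyntheticConfig, line: str, condition: str,
    loci: Optional[List[PlantedLocus]] = None,
) -> Tuple[List[Fragment], List[Peak], pd.DataFrame]:
    """Fragments, peak calls and planted truth for one line x condition.

    Exactly ``cfg.n_fragments`` fragments are returned. Component
    substreams are keyed by (seed, line, component) only — not by
    condition — so parental and treated share their background, baseline
    and negative-control realizations; the treated condition converts a
    slice of the background budget into gain-window signal.
    """
    if line not in LINES or condition not in CONDITIONS:
        raise ValueError(f"unknown line/condition {line!r}/{condition!r}")
    if loci is None:
        loci = plan_loci(cfg)
    li = LINES.index(line)
    bg_peaks = _background_peaks(cfg, line, loci)
    genome_windows = [GenomicInterval(c, 0, l) for c, l in cfg.genome]
    genome_bp = sum(l for _c, l in cfg.genome)

    mine = _loci_for(cfg, loci, line, "treated")  # superset incl. gains
    extra = cfg.enrichment - 1.0
    weights = {"background": float(genome_bp)}
    weights["bg_peaks"] = (cfg.background_peak_enrichment - 1.0) * sum(
        p.length() for p in bg_peaks)
    for l in mine:
        weights[l.locus_id] = extra * sum(w.length() for w in l.windows)
    treated_counts = _allocate(weights, cfg.n_fragments)
    # parental: gain budgets return to the background component
    parental_counts = dict(treated_counts)
    returned = 0
    for l in mine:
        if l.kind in ("shared_gain", "line_gain"):
            returned += parental_counts.pop(l.locus_id)
    parental_counts["background"] += returned
    counts = treated_counts if condition == "treated" else parental_counts

    fragments: List[Fragment] = []
    comp_windows = {"background": genome_windows, "bg_peaks": bg_peaks}
    for l in mine:
        comp_windows[l.locus_id] = list(l.windows)
    for ci, comp in enumerate(sorted(comp_windows)):
        k = counts.get(comp, 0)
        if k == 0:
            continue
        # draw the max over conditions so each condition takes a stream prefix
        k_draw = max(treated_counts.get(comp, 0), parental_counts.get(comp, 0))
        rng = _rng(cfg, 4, li, ci)
        frags = _sample_fragments(rng, comp_windows[comp], k_draw,
                                  cfg.fragment_length, cfg)
        fragments.extend(frags[:k])
    fragments.sort(key=lambda f: (f.interval.chrom, f.interval.start,
                                  f.interval.end, f.strand))

    peaks: List[Peak] = []
    for l in _loci_for(cfg, loci, line, condition):
        for j, w in enumerate(l.windows):
            peaks.append(Peak(w, name=f"{l.locus_id}_p{j + 1}",
                              score=100.0 * cfg.enrichment))
    for j, p in enumerate(bg_peaks):
        peaks.append(Peak(p, name=f"{line}_bg_p{j + 1}",
                          score=100.0 * cfg.background_peak_enrichment))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))

    truth = truth_table(cfg, loci)
    truth = truth[(truth.line == line) & (truth.condition == condition)]
    return fragments, peaks, truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort


def choose_planted_genes(cfg: SyntheticConfig, genes: Sequence[GeneModel],
                         loci: Optional[List[PlantedLocus]] = None) -> List[str]:
    """The gene nearest each shared-gain locus, first ``planted_genes`` of them."""
    if loci is None:
        loci = plan_loci(cfg)
    shared = sorted((l for l in loci if l.kind == "shared_gain"),
                    key=lambda l: (l.hull.chrom, l.hull.start))
    chosen: List[str] = []
    for l in shared:
        near = [g for g in genes if g.interval.chrom == l.hull.chrom]
        if not near:
            continue
        best = min(near, key=lambda g: 0 if g.interval.overlaps(l.hull)
                   else l.hull.distance_to(g.interval))
        if best.symbol not in chosen:
            chosen.append(best.symbol)
        if len(chosen) == cfg.planted_genes:
            break
    if len(chosen) < cfg.planted_genes:
        raise ValueError("could not find enough genes near shared-gain loci")
    return chosen


def simulate_cohort(
    cfg: SyntheticConfig,
    gene_symbols: Sequence[str],
    planted: Sequence[str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor/normal log2 expression and survival with planted effects.

    Expression: per-gene baseline ~ U(3, 8) plus N(0, noise_sd) noise;
    planted genes get +log2_effect in tumors. Survival (tumor samples):
    exponential with hazard ln2/baseline_median times
    hazard_ratio^(number of planted genes with expression above the tumor
    median), censored independently at U(censor_range) days.
    """
    missing = set(planted) - set(gene_symbols)
    if missing:
        raise ValueError(f"planted genes not in gene table: {sorted(missing)}")
    rng = _rng(cfg, 5)
    genes = list(gene_symbols)
    n_g = len(genes)
    tumor_ids = [f"T{i + 1:04d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(cfg.n_normal)]
    n_s = cfg.n_tumor + cfg.n_normal
    baseline = rng.uniform(3, 8, size=n_g)
    values = baseline[:, None] + rng.normal(0, cfg.noise_sd, size=(n_g, n_s))
    planted_idx = [genes.index(g) for g in planted]
    values[np.ix_(planted_idx, range(cfg.n_tumor))] += cfg.log2_effect
    expr = pd.DataFrame(values, index=genes, columns=tumor_ids + normal_ids)

    tumor_vals = expr[tumor_ids]
    lam0 = np.log(2) / cfg.baseline_median_days
    mult = np.ones(cfg.n_tumor)
    for gi in planted_idx:
        row = tumor_vals.iloc[gi].to_numpy()
        high = row > np.median(row)
        mult *= np.where(high, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / (lam0 * mult))
    t_censor = rng.uniform(*cfg.censor_range, size=cfg.n_tumor)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    clinical = pd.DataFrame({
        "sample": tumor_ids + normal_ids,
        "group": ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
        "time": np.round(np.concatenate([time, np.full(cfg.n_normal, np.nan)]), 1),
        "event": np.concatenate([event, np.zeros(cfg.n_normal)]).astype(int),
    })
    return expr, clinical


# ---------------------------------------------------------------------------
# file emission


def write_simulation(cfg: SyntheticConfig, outdir) -> Dict[str, str]:
    """Emit every pipeline input under ``outdir``; returns a path map."""
    from .genomic_io import write_gene_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    sizes, genes = make_genome_and_genes(cfg)
    loci = plan_loci(cfg)

    p = out / "chrom.sizes"
    p.write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))
    paths["chrom_sizes"] = str(p)

    p = out / "genes.tsv"
    write_gene_table(genes, p)
    paths["genes"] = str(p)

    for line in LINES:
        for cond in CONDITIONS:
            frags, peaks, _truth = simulate_chip(cfg, line, cond, loci)
            fp = out / f"fragments_{line}_{cond}.bed"
            with open(fp, "w") as fh:
                for i, f in enumerate(frags):
                    fh.write(
                        f"{f.interval.chrom}\t{f.interval.start}\t"
                        f"{f.interval.end}\tf{i + 1}\t{f.mapq}\t{f.strand}\n")
            paths[f"fragments_{line}_{cond}"] = str(fp)
            pp = out / f"peaks_{line}_{cond}.narrowPeak"
            with open(pp, "w") as fh:
                for pk in peaks:
                    fh.write(
                        f"{pk.interval.chrom}\t{pk.interval.start}\t"
                        f"{pk.interval.end}\t{pk.name}\t{int(pk.score)}\t.\t"
                        f"{pk.score:.1f}\t-1\t-1\t{pk.interval.length() // 2}\n")
            paths[f"peaks_{line}_{cond}"] = str(pp)

    truth = truth_table(cfg, loci)
    tp = out / "truth.tsv"
    truth.to_csv(tp, sep="\t", index=False)
    paths["truth"] = str(tp)

    planted = choose_planted_genes(cfg, genes, loci)
    expr, clinical = simulate_cohort(cfg, [g.symbol for g in genes], planted)
    ep = out / "expr.tsv"
    expr.to_csv(ep, sep="\t", float_format="%.4f")
    paths["expr"] = str(ep)
    cp = out / "clinical.tsv"
    clinical.to_csv(cp, sep="\t", index=False)
    paths["clinical"] = str(cp)
    (out / "planted_genes.txt").write_text("".join(g + "\n" for g in planted))
    paths["planted_genes"] = str(out / "planted_genes.txt")

    # small gene-set file for the enrichment step: the planted set plus decoys
    rng = _rng(cfg, 6)
    symbols = [g.symbol for g in genes]
    with open(out / "gene_sets.gmt", "w") as fh:
        fh.write("planted_pathway\tsynthetic\t" + "\t".join(planted) + "\n")
        for k in range(5):
            decoy = rng.choice(symbols, size=15, replace=False)
            fh.write(f"decoy_set_{k + 1}\tsynthetic\t" + "\t".join(decoy) + "\n")
    paths["gene_sets"] = str(out / "gene_sets.gmt")
    return paths
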