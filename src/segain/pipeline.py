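"""End-to-end orchestration: coverage -> SE calls -> differential ->
intersection -> annotation -> prognostic screen, with a checksummed
manifest so a rerun under the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import coverage as cov
from . import differential_se as diff
from . import gene_annotation as ann
from . import genomic_io as gio
from . import prognostic_screen as screen
from . import se_calling as se

log = logging.getLogger("segain")

LINES = ("A", "B")
CONDITIONS = ("parental", "treated")


@dataclass
class PipelineConfig:
    fragments: Dict[str, Dict[str, str]]  # line -> condition -> path
    peaks: Dict[str, Dict[str, str]]
    genes: str
    expr: str
    clinical: str
    outdir: str
    chrom_sizes: Optional[str] = None
    blacklist: Optional[str] = None
    gene_sets: Optional[str] = None
    extension_length: int = 200
    bin_size: int = 32
    min_mapq: int = 25
    stitch_distance: int = 12_500
    top_fraction: float = 0.05
    annotation_window: int = 50_000
    alpha: float = 0.05
    horizon: int = 1_825
    n_perm: int = 1_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        """Every referenced input must exist before any stage runs."""
        required = {"genes": self.genes, "expr": self.expr,
                    "clinical": self.clinical}
        for line in LINES:
            for cond in CONDITIONS:
                try:
                    required[f"fragments.{line}.{cond}"] = self.fragments[line][cond]
                    required[f"peaks.{line}.{cond}"] = self.peaks[line][cond]
                except KeyError as exc:
                    raise ValueError(
                        f"config missing entry for {line}/{cond}: {exc}") from exc
        for name in ("chrom_sizes", "blacklist", "gene_sets"):
            v = getattr(self, name)
            if v is not None:
                required[name] = v
        for fieldname, p in required.items():
            if not p:
                raise ValueError(f"config field {fieldname!r} is empty")
            if not Path(p).exists():
                raise ValueError(f"config field {fieldname!r}: no such file {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return (and write) the output manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    counts: Dict[str, int] = {}

    cov_params = cov.CoverageParams(
        extension_length=config.extension_length, bin_size=config.bin_size,
        min_mapq=config.min_mapq)
    se_params = se.SECallParams(
        stitch_distance=config.stitch_distance, top_fraction=config.top_fraction)
    sizes = (gio.read_chrom_sizes(config.chrom_sizes)
             if config.chrom_sizes else None)
    blacklist = gio.read_bed(config.blacklist) if config.blacklist else []

    calls: Dict[str, Dict[str, se.SECallResult]] = {}
    for line in LINES:
        calls[line] = {}
        for cond in CONDITIONS:
            stage = f"se_call[{line}/{cond}]"
            try:
                frags = gio.read_fragments(config.fragments[line][cond])
                kept = cov.filter_fragments(frags, cov_params)
                track = cov.build_coverage(kept, cov_params, chrom_sizes=sizes)
                bg_path = out / f"coverage_{line}_{cond}.bedgraph"
                cov.write_bedgraph(track, bg_path)
                outputs[f"coverage_{line}_{cond}"] = str(bg_path)

                peaks = gio.read_narrowpeak(config.peaks[line][cond])
                peaks_kept = se.filter_blacklist(peaks, blacklist)
                regions = se.stitch_peaks(peaks_kept, se_params)
                regions = se.quantify_regions(regions, track)
                result = se.call_superenhancers(regions, se_params)
                calls[line][cond] = result
                se_path = out / f"se_{line}_{cond}.tsv"
                se.write_se_table(result, se_path)
                outputs[f"se_{line}_{cond}"] = str(se_path)
                counts[f"fragments_{line}_{cond}_in"] = len(frags)
                counts[f"fragments_{line}_{cond}_kept"] = len(kept)
                counts[f"peaks_{line}_{cond}"] = len(peaks_kept)
                counts[f"regions_{line}_{cond}"] = len(result.regions)
                counts[f"se_{line}_{cond}"] = result.se_count
                log.info(
                    "%s: %d fragments (%d kept), %d peaks -> %d regions, %d SEs",
                    stage, len(frags), len(kept), len(peaks_kept),
                    len(result.regions), result.se_count)
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage} failed on "
                    f"{config.fragments[line][cond]}: {exc}") from exc

    gains: Dict[str, list] = {}
    for line in LINES:
        stage = f"differential[{line}]"
        try:
            de = diff.classify_gain_loss(calls[line]["treated"],
                                         calls[line]["parental"])
            gains[line] = [d for d in de if d.status == "gained"]
            lost = [d for d in de if d.status == "lost"]
            gp = out / f"gains_{line}.bed"
            gio.write_bed([g.region for g in gains[line]], gp)
            outputs[f"gains_{line}"] = str(gp)
            counts[f"gained_{line}"] = len(gains[line])
            counts[f"lost_{line}"] = len(lost)
            log.info("%s: %d gained, %d lost", stage, len(gains[line]), len(lost))
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "intersect"
    merged = diff.intersect_gains(gains["A"], gains["B"], line_names=LINES)
    mp = out / "merged_regions.tsv"
    diff.write_merged_regions(merged, mp)
    outputs["merged_regions"] = str(mp)
    counts["merged_regions"] = len(merged)
    log.info("%s: %d common gain regions", stage, len(merged))

    stage = "annotate"
    genes = gio.read_gene_table(config.genes)
    ann.annotate_all(merged, genes,
                     ann.AnnotationParams(window=config.annotation_window))
    ap = out / "annotated.tsv"
    ann.write_annotated(merged, ap)
    outputs["annotated"] = str(ap)
    genes_of_interest = sorted({a.gene.symbol for r in merged
                                for a in r.annotations})
    counts["annotated_genes"] = len(genes_of_interest)
    log.info("%s: %d genes over %d regions", stage, len(genes_of_interest),
             len(merged))

    stage = "screen"
    try:
        clinical = pd.read_csv(config.clinical, sep="\t")
        expr = screen.ExpressionMatrix.from_tsv(config.expr, clinical)
        gene_sets = (screen.read_gmt(config.gene_sets)
                     if config.gene_sets else None)
        result = screen.run_screen(
            expr, clinical, genes_of_interest, alpha=config.alpha,
            horizon=config.horizon, gene_sets=gene_sets,
            n_perm=config.n_perm, seed=config.seed)
        sp = out / "screen_genes.tsv"
        result.gene_table.to_csv(sp, sep="\t", index=False,
                                 float_format="%.6g")
        outputs["screen_genes"] = str(sp)
        if result.alterations is not None:
            alt = out / "alterations.tsv"
            result.alterations.to_csv(alt, sep="\t")
            outputs["alterations"] = str(alt)
        if result.exclusivity:
            ep = out / "exclusivity.tsv"
            pd.DataFrame([{
                "gene_a": r.gene_a, "gene_b": r.gene_b,
                "log2_odds_ratio": round(r.log2_odds_ratio, 6),
                "p": f"{r.p:.6g}", "q": f"{r.q:.6g}", "tendency": r.tendency,
            } for r in result.exclusivity]).to_csv(ep, sep="\t", index=False)
            outputs["exclusivity"] = str(ep)
        if result.gsea:
            gp = out / "gsea.tsv"
            pd.DataFrame([{
                "name": r.name, "ES": round(r.es, 6), "NES": round(r.nes, 6),
                "p": f"{r.p:.6g}", "FDR": f"{r.fdr:.6g}",
            } for r in result.gsea]).to_csv(gp, sep="\t", index=False)
            outputs["gsea"] = str(gp)
        for g, curves in result.km_curves.items():
            for arm, table in curves.items():
                kp = out / f"km_{g}_{arm}.tsv"
                table.to_csv(kp, sep="\t", index=False, float_format="%.6g")
                outputs[f"km_{g}_{arm}"] = str(kp)
        counts["upregulated"] = int(result.gene_table["upregulated"].sum())
        counts["prognostic"] = len(result.selected)
        log.info("%s: %d candidates, %d upregulated, %d prognostic", stage,
                 len(result.gene_table), counts["upregulated"],
                 counts["prognostic"])
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed on {config.expr}: {exc}") from exc

    manifest = {
        "params": {k: v for k, v in asdict(config).items()
                   if not isinstance(v, dict)},
        "seed": config.seed,
        "counts": counts,
        "outputs": outputs,
        "checksums": {k: _sha256(v) for k, v in sorted(outputs.items())},
        "selected_genes": result.selected,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
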