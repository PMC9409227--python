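"""Expression/survival/mutual-exclusivity screen for candidate SE genes.

The screen takes the genes annotated to common-gain super-enhancer regions
and asks, in a tumor/normal cohort with follow-up:

1. Which candidates are upregulated in tumors? Welch's two-sided t-test on
   log2 expression, p < alpha and tumor mean > normal mean.
2. Which upregulated candidates are prognostic? Tumors are split at the
   median expression of each gene (ties to the low group), survival is
   administratively censored at a 5-year horizon, and the two groups are
   compared with the standard 1-df log-rank test.
3. How do the prognostic genes co-occur? A tumor is "altered" for a gene
   when its cohort Z-score is >= 0; every gene pair gets a two-sided
   Fisher exact p, a log2 odds ratio (Haldane 0.5 correction when a cell
   is empty) and a Benjamini–Hochberg q over the pair family.
4. What pathways separate altered from non-altered tumors? A preranked
   GSEA (weighted Kolmogorov–Smirnov walk, weight exponent 1) on the log2
   fold change between altered-in-any and non-altered tumors, with a
   seeded gene-label permutation null; NES and FDR are sign-stratified.

Welch/Fisher tests come from scipy, BH from statsmodels, and Kaplan–Meier
/ log-rank from lifelines; the enrichment walk is implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ExclusivityResult",
    "GSEAResult",
    "ScreenResult",
    "filter_upregulated",
    "median_split",
    "truncate_survival",
    "kaplan_meier",
    "logrank_test",
    "alteration_matrix",
    "mutual_exclusivity",
    "bh_adjust",
    "preranked_gsea",
    "alteration_rank_metric",
    "run_screen",
    "read_gmt",
]

FIVE_YEARS_DAYS = 1825


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with tumor/normal labels (log2 scale)."""

    values: pd.DataFrame  # index: gene symbols; columns: sample ids
    sample_labels: pd.Series  # 'tumor' | 'normal', indexed by sample id
    log2: bool = True

    def __post_init__(self) -> None:
        if self.values.index.hasnans or any(g == "" for g in self.values.index):
            raise ValueError("expression matrix has missing gene names")
        unknown = set(self.sample_labels.unique()) - {"tumor", "normal"}
        if unknown:
            raise ValueError(f"unknown sample labels: {sorted(unknown)}")
        self.sample_labels = self.sample_labels.reindex(self.values.columns)
        if self.sample_labels.isna().any():
            raise ValueError("every sample column needs a tumor/normal label")

    def samples(self, label: str) -> List[str]:
        return list(self.sample_labels.index[self.sample_labels == label])

    @property
    def tumor(self) -> pd.DataFrame:
        return self.values[self.samples("tumor")]

    @property
    def normal(self) -> pd.DataFrame:
        return self.values[self.samples("normal")]

    @classmethod
    def from_tsv(cls, expr_path, clinical: pd.DataFrame) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        labels = clinical.set_index("sample")["group"]
        return cls(values=values, sample_labels=labels)


@dataclass(frozen=True)
class ExclusivityResult:
    gene_a: str
    gene_b: str
    log2_odds_ratio: float
    p: float
    q: float
    tendency: str  # co-occurrence | mutual exclusivity
    table: Tuple[int, int, int, int]  # (both, a_only, b_only, neither)


@dataclass(frozen=True)
class GSEAResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: Tuple[str, ...]


# ---------------------------------------------------------------------------
# 1. upregulation filter


def filter_upregulated(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    genes: Optional[Sequence[str]] = None,
) -> List[str]:
    """Genes upregulated in tumors: Welch p < alpha AND tumor mean > normal mean."""
    tumor, normal = expr.tumor, expr.normal
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples in each group for Welch's t-test")
    index = expr.values.index if genes is None else [
        g for g in genes if g in expr.values.index
    ]
    t_vals = tumor.loc[index].to_numpy()
    n_vals = normal.loc[index].to_numpy()
    _stat, p = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=False)
    up = t_vals.mean(axis=1) > n_vals.mean(axis=1)
    return [g for g, pv, u in zip(index, p, up) if u and pv < alpha]


# ---------------------------------------------------------------------------
# 2. survival


def median_split(values: pd.Series) -> Tuple[List[str], List[str]]:
    """Split samples at the median: value > median -> high, else low.

    Raises when either group would be empty (degenerate, e.g. constant
    expression).
    """
    if len(values) < 2:
        raise ValueError("median split needs >= 2 samples")
    med = float(values.median())
    high = list(values.index[values > med])
    low = list(values.index[values <= med])
    if not high or not low:
        raise ValueError("degenerate median split: one group is empty")
    return high, low


def truncate_survival(clinical: pd.DataFrame, horizon: int = FIVE_YEARS_DAYS
                      ) -> pd.DataFrame:
    """Administratively censor at ``horizon`` days (event -> 0 past horizon)."""
    out = clinical.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def kaplan_meier(clinical: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate; returns a (time, survival) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(clinical["time"], clinical["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame
                 ) -> Tuple[float, float]:
    """Standard 1-df log-rank chi-square and p for two survival groups."""
    if int(group_a["event"].sum() + group_b["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# 3. alteration + mutual exclusivity


def alteration_matrix(tumor_expr: pd.DataFrame) -> pd.DataFrame:
    """Binary genes x tumor-samples matrix: altered iff cohort Z-score >= 0.

    Z is computed per gene against the whole tumor cohort's mean and sd on
    log2 values; a zero-variance gene has no defined Z and raises.
    """
    if tumor_expr.shape[1] < 2:
        raise ValueError("alteration matrix needs >= 2 tumor samples")
    sd = tumor_expr.std(axis=1, ddof=1)
    if (sd == 0).any():
        dead = list(tumor_expr.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {dead}")
    z = tumor_expr.sub(tumor_expr.mean(axis=1), axis=0).div(sd, axis=0)
    return (z >= 0).astype(int)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    if len(pvals) == 0:
        return np.array([])
    return multipletests(pvals, method="fdr_bh")[1]


def mutual_exclusivity(mat: pd.DataFrame) -> List[ExclusivityResult]:
    """Pairwise co-occurrence/mutual-exclusivity over alteration calls.

    Per unordered gene pair: 2x2 table (both altered, a only, b only,
    neither), two-sided Fisher exact p, log2 odds ratio with Haldane 0.5
    correction when any cell is zero, BH q over all pairs; tendency is
    co-occurrence when OR > 1, else mutual exclusivity.
    """
    if mat.shape[0] < 2:
        raise ValueError("mutual exclusivity needs >= 2 genes")
    rows = []
    for ga, gb in itertools.combinations(mat.index, 2):
        va, vb = mat.loc[ga].to_numpy(), mat.loc[gb].to_numpy()
        a = int(((va == 1) & (vb == 1)).sum())
        b = int(((va == 1) & (vb == 0)).sum())
        c = int(((va == 0) & (vb == 1)).sum())
        d = int(((va == 0) & (vb == 0)).sum())
        _or, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append((ga, gb, float(np.log2(odds)), float(p), (a, b, c, d)))
    qs = bh_adjust([r[3] for r in rows])
    out = []
    for (ga, gb, log_or, p, table), q in zip(rows, qs):
        out.append(
            ExclusivityResult(
                gene_a=ga, gene_b=gb, log2_odds_ratio=log_or, p=p, q=float(q),
                tendency="co-occurrence" if log_or > 0 else "mutual exclusivity",
                table=table,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 4. preranked GSEA


def _es_walk(order_scores: np.ndarray, hit_mask: np.ndarray) -> Tuple[float, int]:
    """Signed max-deviation enrichment score of a hit mask over a ranking.

    ``order_scores`` are the ranking metric values in rank order; hits are
    weighted by |score|^1, misses by 1/(N - nh). Returns (ES, position of
    the extremum).
    """
    nh = int(hit_mask.sum())
    n = len(order_scores)
    weights = np.abs(order_scores) * hit_mask
    denom = weights.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted hits
        weights = hit_mask.astype(float)
        denom = weights.sum()
    p_hit = np.cumsum(weights) / denom
    p_miss = np.cumsum(~hit_mask) / (n - nh)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def preranked_gsea(
    scores: pd.Series,
    gene_sets: Dict[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> List[GSEAResult]:
    """Preranked gene-set enrichment with a gene-label permutation null.

    ``scores`` maps gene -> ranking metric (sorted internally, descending).
    Sets with < 2 members present in the ranking are skipped with a
    warning. Nominal p and NES are computed against same-sign permuted
    enrichment scores; FDR compares the observed NES distribution with
    the pooled permuted NES distribution, sign-stratified.
    """
    import warnings

    ranked = scores.sort_values(ascending=False)
    genes = list(ranked.index)
    vals = ranked.to_numpy(dtype=float)
    n = len(genes)
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept = []
    for name, members in gene_sets.items():
        idx = sorted({index_of[g] for g in members if g in index_of})
        if len(idx) < 2 or len(idx) >= n:
            warnings.warn(f"gene set {name!r}: <2 members in ranking, skipped")
            continue
        kept.append((name, idx))

    results = []
    null_nes_pool: List[float] = []
    obs = []
    for name, idx in kept:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, extreme = _es_walk(vals, mask)
        null = np.empty(n_perm)
        k = len(idx)
        for j in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=k, replace=False)] = True
            null[j], _ = _es_walk(vals, perm)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            p, nes, nes_null = 1.0, 0.0, np.array([])
        else:
            p = float((np.abs(same_sign) >= abs(es)).sum() + 1) / (len(same_sign) + 1)
            mean_abs = float(np.abs(same_sign).mean())
            nes = es / mean_abs if mean_abs > 0 else 0.0
            nes_null = same_sign / mean_abs
        null_nes_pool.extend(nes_null.tolist())
        if es >= 0:
            leading = tuple(g for i, g in enumerate(genes[: extreme + 1]) if mask[i])
        else:
            leading = tuple(g for i, g in enumerate(genes) if i >= extreme and mask[i])
        obs.append((name, es, nes, p, leading))

    pool = np.asarray(null_nes_pool)
    obs_nes = np.array([o[2] for o in obs])
    for name, es, nes, p, leading in obs:
        if len(pool) == 0:
            fdr = 1.0
        elif nes >= 0:
            num = float((pool >= nes).mean())
            den = float((obs_nes >= nes).mean())
            fdr = min(1.0, num / den) if den > 0 else 1.0
        else:
            num = float((pool <= nes).mean())
            den = float((obs_nes <= nes).mean())
            fdr = min(1.0, num / den) if den > 0 else 1.0
        results.append(GSEAResult(name=name, es=es, nes=nes, p=p, fdr=fdr,
                                  leading_edge=leading))
    return results


def alteration_rank_metric(tumor_expr: pd.DataFrame, altered_any: pd.Series
                           ) -> pd.Series:
    """log2 fold change (difference of log2 means) altered vs non-altered."""
    altered_any = altered_any.reindex(tumor_expr.columns).astype(bool)
    if altered_any.all() or (~altered_any).all():
        raise ValueError("both altered and non-altered groups must be non-empty")
    return (
        tumor_expr.loc[:, altered_any].mean(axis=1)
        - tumor_expr.loc[:, ~altered_any].mean(axis=1)
    )


def read_gmt(path) -> Dict[str, List[str]]:
    """Read GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ScreenResult:
    gene_table: pd.DataFrame  # per-candidate statistics
    selected: List[str]  # upregulated AND log-rank p < alpha
    alterations: Optional[pd.DataFrame]
    exclusivity: List[ExclusivityResult]
    gsea: List[GSEAResult]
    km_curves: Dict[str, Dict[str, pd.DataFrame]]


def run_screen(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    genes_of_interest: Sequence[str],
    alpha: float = 0.05,
    horizon: int = FIVE_YEARS_DAYS,
    gene_sets: Optional[Dict[str, Sequence[str]]] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """The full candidate-gene screen.

    ``clinical`` needs columns sample/group/time/event; survival is only
    defined for tumor samples. Steps: upregulation filter over the
    candidates, per-gene median-split log-rank at the horizon, Z >= 0
    alteration matrix and pairwise exclusivity over the prognostic genes,
    and (when gene sets are supplied) preranked GSEA on the altered vs
    non-altered contrast.
    """
    candidates = [g for g in genes_of_interest if g in expr.values.index]
    upregulated = set(filter_upregulated(expr, alpha=alpha, genes=candidates))

    tumor = expr.tumor
    surv = clinical[clinical["group"] == "tumor"].set_index("sample")
    surv = surv.loc[[s for s in tumor.columns if s in surv.index]]
    surv5 = truncate_survival(surv.reset_index(), horizon=horizon).set_index("sample")

    rows = []
    km_curves: Dict[str, Dict[str, pd.DataFrame]] = {}
    selected = []
    for g in candidates:
        rec = {"gene": g, "upregulated": g in upregulated,
               "logrank_stat": np.nan, "logrank_p": np.nan, "selected": False}
        if g in upregulated:
            values = tumor.loc[g, surv5.index]
            try:
                high, low = median_split(values)
            except ValueError:
                rows.append(rec)
                continue
            a, b = surv5.loc[high], surv5.loc[low]
            try:
                stat, p = logrank_test(a, b)
            except ValueError:
                rows.append(rec)
                continue
            rec.update(logrank_stat=stat, logrank_p=p, selected=p < alpha)
            if p < alpha:
                selected.append(g)
                km_curves[g] = {"high": kaplan_meier(a), "low": kaplan_meier(b)}
        rows.append(rec)
    gene_table = pd.DataFrame(
        rows, columns=["gene", "upregulated", "logrank_stat", "logrank_p",
                       "selected"])

    alterations = None
    exclusivity: List[ExclusivityResult] = []
    gsea_results: List[GSEAResult] = []
    if len(selected) >= 2:
        alterations = alteration_matrix(tumor.loc[selected])
        exclusivity = mutual_exclusivity(alterations)
        if gene_sets:
            altered_any = alterations.any(axis=0)
            metric = alteration_rank_metric(tumor, altered_any)
            gsea_results = preranked_gsea(metric, gene_sets, n_perm=n_perm,
                                          seed=seed)
    return ScreenResult(
        gene_table=gene_table, selected=selected, alterations=alterations,
        exclusivity=exclusivity, gsea=gsea_results, km_curves=km_curves,
    )
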