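"""The NET-associated regulatory gene (NRG) discovery cascade.

Stages, in pipeline order:

1. per-cancer-type Pearson screen of every candidate gene against the
   NET score (qualifying pair: |R| above threshold and p significant);
2. recurrence filter — a gene is "core" for a survival class when it
   forms qualifying pairs in at least ``recurrence_min`` cancer types of
   that class;
3. exclusivity filter on positive-sign pairs — genes recurrently
   positive in one class and (almost) absent from the other;
4. differential expression of the shortlisted genes between the pooled
   poor-class and favorable-class tumors;
5. nomination of the key gene (the SPP1 analog): the poor-exclusive gene
   that is significantly over-expressed in poor-class tumors, ranked by
   fold change, recurrence and mean correlation;
6. pan-cancer hazard sweep and combined NET x gene survival
   stratification (high/high vs low/low Cox contrast).

:func:`run_pipeline` chains all stages on aligned inputs and optionally
writes every intermediate as a tab-separated table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from .association_stats import de_test, vectorized_pearson
from .core_io import AnalysisConfig, ExpressionMatrix, GeneSetCollection, align
from .enrichment_scoring import gsva_scores
from .survival_models import (
    CoxFit,
    classify_net_survival,
    cox_univariate,
    optimal_cutpoint,
)

logger = logging.getLogger("netscreen")

__all__ = [
    "nrg_pairs",
    "recurrence_filter",
    "exclusivity_filter",
    "core_sets",
    "class_de",
    "nominate_key_gene",
    "pan_cancer_hr_sweep",
    "combined_stratification",
    "CombinedStrataResult",
    "PipelineResult",
    "run_pipeline",
]

MIN_SAMPLES_PER_TYPE = 10


def nrg_pairs(
    net_scores: pd.Series,
    expr: ExpressionMatrix,
    cancer_types: pd.Series,
    cfg: AnalysisConfig | None = None,
    exclude=(),
) -> pd.DataFrame:
    """Per-cancer-type NET-score / gene correlation pairs.

    For every cancer type with at least 10 scored samples, computes the
    Pearson correlation of each candidate gene (``exclude`` — normally
    the signature itself — removed) with the NET score and keeps pairs
    with |r| > ``cfg.r_nrg`` and p < ``cfg.p_sig``.
    """
    cfg = cfg or AnalysisConfig()
    excluded = set(exclude)
    candidates = [g for g in expr.gene_ids if g not in excluded]
    sub = expr.data.loc[candidates]
    rows = []
    for ctype in pd.unique(cancer_types):
        samples = [
            s for s, t in cancer_types.items() if t == ctype and s in net_scores.index
        ]
        if len(samples) < MIN_SAMPLES_PER_TYPE:
            warnings.warn(
                f"cancer type {ctype}: only {len(samples)} scored sample(s); skipped"
            )
            continue
        y = net_scores.loc[samples].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"cancer type {ctype}: constant NET score; skipped")
            continue
        r, p = vectorized_pearson(sub.loc[:, samples].to_numpy(), y)
        keep = np.isfinite(r) & (np.abs(r) > cfg.r_nrg) & (p < cfg.p_sig)
        for gi in np.nonzero(keep)[0]:
            rows.append(
                {
                    "cancer_type": ctype,
                    "gene": candidates[gi],
                    "r": float(r[gi]),
                    "p": float(p[gi]),
                    "sign": "+" if r[gi] > 0 else "-",
                }
            )
    return pd.DataFrame(rows, columns=["cancer_type", "gene", "r", "p", "sign"])


def recurrence_filter(
    pairs: pd.DataFrame,
    classes: pd.Series,
    cfg: AnalysisConfig | None = None,
):
    """Count qualifying pairs per gene within each survival class.

    ``classes`` maps cancer type -> {favorable, poor, neutral}; neutral
    types contribute to neither count.  A gene is core for a class when
    it has qualifying pairs in at least ``cfg.recurrence_min`` cancer
    types of that class; pairs of genes that are core in neither class
    are dropped.  Positive-sign counts are tracked separately for the
    exclusivity filter.  Returns ``(core_pairs, summary)``.
    """
    cfg = cfg or AnalysisConfig()
    classes = pd.Series(classes)
    if pairs.empty:
        summary = pd.DataFrame(
            columns=["count_fav", "count_poor", "pos_count_fav", "pos_count_poor",
                     "core_fav", "core_poor", "exclusivity"]
        )
        return pairs.copy(), summary
    missing = set(pairs["cancer_type"]) - set(classes.index)
    if missing:
        raise ValueError(f"no survival class for cancer type(s): {sorted(missing)}")
    tagged = pairs.assign(cls=classes.loc[pairs["cancer_type"]].to_numpy())
    classed = tagged[tagged["cls"].isin(["favorable", "poor"])]

    def count(frame, cls):
        sel = frame[frame["cls"] == cls]
        return sel.groupby("gene")["cancer_type"].nunique()

    genes = sorted(classed["gene"].unique())
    summary = pd.DataFrame(index=pd.Index(genes, name="gene"))
    summary["count_fav"] = count(classed, "favorable").reindex(genes).fillna(0).astype(int)
    summary["count_poor"] = count(classed, "poor").reindex(genes).fillna(0).astype(int)
    pos = classed[classed["sign"] == "+"]
    summary["pos_count_fav"] = count(pos, "favorable").reindex(genes).fillna(0).astype(int)
    summary["pos_count_poor"] = count(pos, "poor").reindex(genes).fillna(0).astype(int)
    summary["core_fav"] = summary["count_fav"] >= cfg.recurrence_min
    summary["core_poor"] = summary["count_poor"] >= cfg.recurrence_min

    def exclusivity(row):
        if (row["pos_count_poor"] >= cfg.exclusive_in_min
                and row["pos_count_fav"] <= cfg.exclusive_out_max):
            return "poor_exclusive"
        if (row["pos_count_fav"] >= cfg.exclusive_in_min
                and row["pos_count_poor"] <= cfg.exclusive_out_max):
            return "fav_exclusive"
        if row["core_fav"] and row["core_poor"]:
            return "shared"
        return "none"

    summary["exclusivity"] = summary.apply(exclusivity, axis=1)

    core_genes = {}
    for cls, flag in (("favorable", "core_fav"), ("poor", "core_poor")):
        core_genes[cls] = set(summary.index[summary[flag]])
    keep = classed.apply(
        lambda row: row["gene"] in core_genes.get(row["cls"], ()), axis=1
    )
    core_pairs = classed.loc[keep, ["cancer_type", "gene", "r", "p", "sign"]]
    return core_pairs.reset_index(drop=True), summary


def core_sets(summary: pd.DataFrame) -> dict[str, set[str]]:
    """Core gene sets per class plus their overlap and set differences."""
    fav = set(summary.index[summary.get("core_fav", pd.Series(dtype=bool))])
    poor = set(summary.index[summary.get("core_poor", pd.Series(dtype=bool))])
    return {
        "favorable_core": fav,
        "poor_core": poor,
        "overlap": fav & poor,
        "favorable_only": fav - poor,
        "poor_only": poor - fav,
    }


def exclusivity_filter(
    summary: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> dict[str, list[str]]:
    """Class-exclusive shortlists from the positive-pair recurrence counts."""
    if summary.empty:
        return {"poor": [], "favorable": []}
    return {
        "poor": sorted(summary.index[summary["exclusivity"] == "poor_exclusive"]),
        "favorable": sorted(summary.index[summary["exclusivity"] == "fav_exclusive"]),
    }


def class_de(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    classes: pd.Series,
    genes=None,
) -> pd.DataFrame:
    """Welch differential expression of pooled poor-class vs pooled
    favorable-class tumor samples (restricted to ``genes`` if given).

    Positive ``logfc`` = higher in poor-class tumors.
    """
    classes = pd.Series(classes)
    tumors = clinical[clinical["tissue"] == "tumor"]
    cls_of = classes.reindex(tumors["cancer_type"]).to_numpy()
    poor_samples = list(tumors.loc[cls_of == "poor", "sample"])
    fav_samples = list(tumors.loc[cls_of == "favorable", "sample"])
    poor_samples = [s for s in poor_samples if s in set(expr.sample_ids)]
    fav_samples = [s for s in fav_samples if s in set(expr.sample_ids)]
    if genes is not None:
        genes = [g for g in genes if g in set(expr.gene_ids)]
        if len(genes) == 0:
            warnings.warn("empty shortlist; no differential expression computed")
            return pd.DataFrame(columns=["logfc", "t", "p", "p_adj"])
        if len(genes) == 1:
            # de_test requires a 2+-gene matrix; pad with a throwaway gene
            pad = next(g for g in expr.gene_ids if g != genes[0])
            out = de_test(expr.subset_genes([genes[0], pad]), poor_samples, fav_samples)
            return out.loc[[genes[0]]]
        expr = expr.subset_genes(genes)
    return de_test(expr, poor_samples, fav_samples)


def nominate_key_gene(
    shortlist: dict[str, list[str]],
    de: pd.DataFrame,
    pairs: pd.DataFrame,
    classes: pd.Series,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Rank poor-exclusive genes and nominate the key gene.

    The nominee must look like the screen's target: recurrently and
    positively NET-correlated in poor-survival cancer types while
    over-expressed there.  Ranking keys, lexicographically descending:
    significant over-expression in poor-class tumors (BH p < p_sig and
    log2 fold change >= log2(fc_min)), then fold change, then the number
    of poor-class cancer types with a positive qualifying pair, then the
    mean r across those types; gene name breaks residual ties.
    """
    cfg = cfg or AnalysisConfig()
    genes = list(shortlist.get("poor", []))
    if not genes:
        raise ValueError(
            "no poor-exclusive genes to nominate "
            f"(shortlist sizes: {({k: len(v) for k, v in shortlist.items()})})"
        )
    classes = pd.Series(classes)
    poor_types = set(classes.index[classes == "poor"])
    pos_poor = pairs[
        (pairs["sign"] == "+")
        & pairs["cancer_type"].isin(poor_types)
        & pairs["gene"].isin(genes)
    ]
    count = pos_poor.groupby("gene")["cancer_type"].nunique()
    mean_r = pos_poor.groupby("gene")["r"].mean()
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    table["count_poor"] = count.reindex(genes).fillna(0).astype(int)
    table["mean_r_poor"] = mean_r.reindex(genes).fillna(0.0)
    table["logfc"] = de["logfc"].reindex(genes).fillna(0.0)
    table["p_adj"] = de["p_adj"].reindex(genes).fillna(1.0)
    table["de_up"] = (table["p_adj"] < cfg.p_sig) & (
        table["logfc"] >= np.log2(cfg.fc_min)
    )
    table = table.sort_values(
        by=["de_up", "logfc", "count_poor", "mean_r_poor", "gene"],
        ascending=[False, False, False, False, True],
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def pan_cancer_hr_sweep(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    genes,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Univariate Cox hazard ratio per gene, dichotomized at the gene's
    mean expression over the pooled survival samples.

    Genes whose dichotomy is degenerate (all samples on one side) are
    skipped with a warning.
    """
    cfg = cfg or AnalysisConfig()
    surv = clinical.dropna(subset=["time", "event"])
    surv = surv[surv["sample"].isin(set(expr.sample_ids))]
    samples = list(surv["sample"])
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=float)
    rows = []
    for gene in genes:
        if gene not in set(expr.gene_ids):
            warnings.warn(f"gene {gene!r} not in matrix; skipped")
            continue
        vals = expr.data.loc[gene, samples].to_numpy(dtype=float)
        high = (vals > vals.mean()).astype(float)
        if high.sum() == 0 or high.sum() == len(high):
            warnings.warn(f"gene {gene!r}: degenerate mean split; skipped")
            continue
        fit = cox_univariate(time, event, high)
        rows.append(
            {"gene": gene, "beta": fit.beta, "hr": fit.hr, "p": fit.p,
             "converged": fit.converged, "n": fit.n, "n_events": fit.n_events,
             "significant": bool(fit.converged and fit.p < cfg.p_sig)}
        )
    return pd.DataFrame(rows, columns=["gene", "beta", "hr", "p", "converged",
                                       "n", "n_events", "significant"])


@dataclass
class CombinedStrataResult:
    """Joint NET x gene stratification with the high/high vs low/low contrast."""

    groups: pd.Series  # per-sample label in {high/high, high/low, low/high, low/low}
    cox: CoxFit  # high/high vs low/low (reference = low/low)
    logrank_p: float  # 4-group log-rank across all strata
    net_cutoff: float
    gene_cutoff: float


def combined_stratification(
    net_scores: pd.Series,
    gene_expr: pd.Series,
    clinical: pd.DataFrame,
    cutoff: str = "median",
    cfg: AnalysisConfig | None = None,
) -> CombinedStrataResult:
    """Stratify samples jointly by NET score and one gene's expression.

    Each feature is dichotomized (``median`` by default; ``mean`` and
    ``optimal`` cutpoints available), samples fall into four joint
    groups, and the Cox contrast compares high/high against low/low
    (the two mixed groups are excluded from that contrast).  A 4-group
    log-rank p across all strata is also reported.  Any empty joint
    group is an error.
    """
    cfg = cfg or AnalysisConfig()
    surv = clinical.dropna(subset=["time", "event"])
    samples = [
        s for s in surv["sample"]
        if s in net_scores.index and s in gene_expr.index
    ]
    if len(samples) < 20:
        raise ValueError("need at least 20 samples with survival for stratification")
    surv = surv.set_index("sample").loc[samples]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=float)
    net = net_scores.loc[samples].to_numpy(dtype=float)
    gx = gene_expr.loc[samples].to_numpy(dtype=float)
    if np.ptp(net) == 0 or np.ptp(gx) == 0:
        raise ValueError("both features must be non-constant")

    def cut(values):
        if cutoff == "median":
            return float(np.median(values))
        if cutoff == "mean":
            return float(values.mean())
        if cutoff == "optimal":
            return optimal_cutpoint(
                values, time, event, cfg.cutpoint_quantile_range
            ).threshold
        raise ValueError(f"unknown cutoff rule {cutoff!r}")

    net_cut, gene_cut = cut(net), cut(gx)
    net_high = net > net_cut
    gene_high = gx > gene_cut
    label = np.where(
        net_high & gene_high, "high/high",
        np.where(net_high, "high/low", np.where(gene_high, "low/high", "low/low")),
    )
    for grp in ("high/high", "high/low", "low/high", "low/low"):
        if not (label == grp).any():
            raise ValueError(f"joint group {grp!r} is empty")
    groups = pd.Series(label, index=samples, name="joint_group")

    contrast = (label == "high/high") | (label == "low/low")
    fit = cox_univariate(
        time[contrast], event[contrast], (label[contrast] == "high/high").astype(float)
    )
    lr = multivariate_logrank_test(time, label, event)
    return CombinedStrataResult(
        groups=groups, cox=fit, logrank_p=float(lr.p_value),
        net_cutoff=net_cut, gene_cutoff=gene_cut,
    )


@dataclass
class PipelineResult:
    """Everything the end-to-end screen produces."""

    net_scores: pd.Series
    survival_classes: pd.DataFrame
    pairs: pd.DataFrame
    core_pairs: pd.DataFrame
    summary: pd.DataFrame
    shortlist: dict[str, list[str]]
    de: pd.DataFrame | None
    nominee_table: pd.DataFrame | None
    nominee: str | None
    strata: CombinedStrataResult | None


def score_per_cancer_type(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    sets: GeneSetCollection,
    signature_name: str = "NET_SIGNATURE",
    tumor_only: bool = True,
) -> pd.Series:
    """GSVA NET score computed within each cancer type separately.

    Scoring per type keeps the kernel CDFs and rank walks inside one
    cohort, mirroring a per-cancer analysis and avoiding cross-type
    batch structure.
    """
    signature = GeneSetCollection({signature_name: sets[signature_name]})
    pieces = []
    frame = clinical[clinical["tissue"] == "tumor"] if tumor_only else clinical
    for ctype, sub in frame.groupby("cancer_type", sort=True):
        samples = [s for s in sub["sample"] if s in set(expr.sample_ids)]
        if len(samples) < 3:
            warnings.warn(f"cancer type {ctype}: fewer than 3 samples; not scored")
            continue
        scores = gsva_scores(expr.subset_samples(samples), signature)
        pieces.append(scores.loc[signature_name])
    if not pieces:
        raise ValueError("no cancer type had enough samples to score")
    out = pd.concat(pieces)
    out.name = "net_score"
    return out


def run_pipeline(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    sets: GeneSetCollection,
    cfg: AnalysisConfig | None = None,
    out_dir=None,
    signature_name: str = "NET_SIGNATURE",
) -> PipelineResult:
    """Run the full cascade: score -> classify -> pair -> filter -> DE ->
    nominate -> stratify.

    Deterministic for fixed inputs and config.  With ``out_dir`` every
    intermediate is written as a tab-separated table tagged with the
    config hash and seed.
    """
    cfg = cfg or AnalysisConfig()
    expr, clinical = align(expr, clinical)
    tumors = clinical[clinical["tissue"] == "tumor"]

    net_scores = score_per_cancer_type(expr, clinical, sets, signature_name)
    surv_classes = classify_net_survival(net_scores, tumors, cfg)
    classes = surv_classes["class"]

    signature_genes = sets[signature_name]
    tumor_expr = expr.subset_samples(
        [s for s in tumors["sample"] if s in net_scores.index]
    )
    ctype = tumors.set_index("sample")["cancer_type"]
    pairs = nrg_pairs(net_scores, tumor_expr, ctype, cfg, exclude=signature_genes)
    core_pairs, summary = recurrence_filter(pairs, classes, cfg)
    shortlist = exclusivity_filter(summary, cfg)

    de = nominee_table = strata = None
    nominee = None
    union = sorted(set(shortlist["poor"]) | set(shortlist["favorable"]))
    if not union:
        warnings.warn("empty shortlist: no class-exclusive NRGs found")
    else:
        de = class_de(expr, clinical, classes, genes=union)
        if shortlist["poor"]:
            nominee_table = nominate_key_gene(shortlist, de, pairs, classes, cfg)
            nominee = str(nominee_table.index[0])
            try:
                strata = combined_stratification(
                    net_scores, expr.data.loc[nominee], tumors, "median", cfg
                )
            except ValueError as exc:
                warnings.warn(f"combined stratification failed: {exc}")
        else:
            warnings.warn("no poor-exclusive genes; key-gene nomination skipped")

    result = PipelineResult(
        net_scores=net_scores, survival_classes=surv_classes, pairs=pairs,
        core_pairs=core_pairs, summary=summary, shortlist=shortlist,
        de=de, nominee_table=nominee_table, nominee=nominee, strata=strata,
    )
    if out_dir is not None:
        _write_outputs(result, cfg, out_dir)
    return result


def _write_outputs(result: PipelineResult, cfg: AnalysisConfig, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = f"config={cfg.config_hash()} seed={cfg.seed}"

    def dump(obj, name, **kwargs):
        with open(out / name, "w") as fh:
            fh.write(f"# {meta}\n")
            obj.to_csv(fh, sep="\t", **kwargs)

    dump(result.net_scores, "net_scores.tsv", header=True)
    dump(result.survival_classes, "survival_class.tsv")
    dump(result.pairs, "nrg_pairs.tsv", index=False)
    dump(result.summary, "screen_summary.tsv")
    shortlist_df = pd.DataFrame(
        [(cls, g) for cls, genes in result.shortlist.items() for g in genes],
        columns=["class", "gene"],
    )
    dump(shortlist_df, "shortlist.tsv", index=False)
    if result.nominee_table is not None:
        dump(result.nominee_table, "nominee.tsv")
    if result.strata is not None:
        dump(result.strata.groups, "combined_strata.tsv", header=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"{meta}\n")
        fh.write(f"nominee={result.nominee}\n")
        if result.strata is not None:
            fh.write(
                f"combined_hr={result.strata.cox.hr:.4f} "
                f"p={result.strata.cox.p:.3g}\n"
            )
    logger.info("pipeline outputs written to %s", out)
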