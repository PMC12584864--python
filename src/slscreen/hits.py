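"""Hit calling for paired-background synthetic-lethality screens.

The cascade turns per-pipeline gene scores into a final candidate list:

1. class assignment per (gene, comparison, pipeline) from CS and p-value —
   depleted (CS < -0.5, p < 0.05), enriched (CS > 0.5, p < 0.05), or
   static (|CS| <= 0.5);
2. expression filter (genes not expressed in the cell model are dropped);
3. trend selection — a candidate must be depleted in the differential
   MUT-vs-WT-final contrast (MUT*) and additionally show one of three
   (MUT, WT) patterns: (1) static/enriched, (2) depleted/enriched,
   (3) depleted/static — i.e. it drops out in the mutant background but
   not in the wild type;
4. consensus across scoring pipelines (kept if flagged by >= 2 of 3);
5. quartile-separation filter on per-sgRNA Z-scores — the third quartile
   of the gene's guides in the mutant final samples must lie strictly
   below the first quartile in both WT day-1 and WT final samples, which
   demands absolute dropout in the mutant rather than relative movement.

On the significance requirement for "static": the class is meant to capture
genes that do *not significantly change*, so by default it requires only
|CS| <= 0.5.  The stricter variant (also requiring p < 0.05, i.e. a
significantly-nonzero-yet-small effect) is available via
``static_requires_significance=True``; under that reading a true null gene
is almost never classified at all, and trends (1) and (3) become nearly
unreachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .library import SgRNALibrary
from .scoring import (
    ComparisonSpec,
    default_comparisons,
    normalize_counts,
    run_pipelines,
    sgrna_zscores,
)

GENE_CLASSES = ("depleted", "enriched", "static", "unclassified")

#: the three accepted (MUT, WT) patterns, all requiring MUT* = depleted
TRENDS: Mapping[int, tuple[str, str]] = {
    1: ("static", "enriched"),
    2: ("depleted", "enriched"),
    3: ("depleted", "static"),
}


@dataclass(frozen=True)
class HitCallConfig:
    """Thresholds and switches of the hit-calling cascade."""

    cs_cut: float = 0.5
    alpha: float = 0.05
    use_adjusted_p: bool = True
    min_pipelines: int = 2
    expression_threshold: float = 1.0
    quartile_filter: bool = True
    static_requires_significance: bool = False

    def __post_init__(self) -> None:
        if self.cs_cut <= 0:
            raise ValueError("cs_cut must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_pipelines < 1:
            raise ValueError("min_pipelines must be >= 1")


def classify_gene(cs: float, p: float, config: HitCallConfig = HitCallConfig()) -> str:
    """Assign depleted / enriched / static / unclassified from CS and p."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    significant = p < config.alpha
    if cs < -config.cs_cut and significant:
        return "depleted"
    if cs > config.cs_cut and significant:
        return "enriched"
    if abs(cs) <= config.cs_cut and (significant or not config.static_requires_significance):
        return "static"
    return "unclassified"


def classify_scores(scores: pd.DataFrame, config: HitCallConfig = HitCallConfig()) -> pd.DataFrame:
    """Vectorised class assignment on a long-format score table."""
    p = scores["p_adj"] if config.use_adjusted_p else scores["p"]
    out = scores.copy()
    out["gene_class"] = [
        classify_gene(cs, pv, config) for cs, pv in zip(scores["cs"], p)
    ]
    return out


def expression_filter(
    genes: Sequence[str], expression: pd.DataFrame, threshold: float = 1.0
) -> list[str]:
    """Retain genes with expression >= threshold; missing genes are treated
    as unexpressed (with a warning)."""
    table = expression.set_index("gene")["expression"]
    missing = [g for g in genes if g not in table.index]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from the expression table are "
            "treated as unexpressed",
            stacklevel=2,
        )
    return [g for g in genes if g in table.index and table[g] >= threshold]


def trend_id(mut_star: str, mut: str, wt: str) -> int | None:
    """Trend number (1-3) matched by a class triple, or None."""
    if mut_star != "depleted":
        return None
    for tid, (mut_req, wt_req) in TRENDS.items():
        if mut == mut_req and wt == wt_req:
            return tid
    return None


def select_trend_hits(classes: pd.DataFrame) -> pd.DataFrame:
    """Apply the three-trend predicate per gene.

    ``classes`` must hold one row per (gene, comparison) with a
    ``gene_class`` column covering all three comparisons; returns
    ``gene  hit  trend``.
    """
    wide = classes.pivot_table(
        index="gene", columns="comparison", values="gene_class", aggfunc="first"
    )
    missing = {"WT", "MUT", "MUT_star"} - set(wide.columns)
    if missing:
        raise ValueError(f"missing comparison(s): {sorted(missing)}")
    rows = []
    for gene, row in wide.iterrows():
        tid = trend_id(row["MUT_star"], row["MUT"], row["WT"])
        rows.append((gene, tid is not None, tid))
    return pd.DataFrame(rows, columns=["gene", "hit", "trend"])


def consensus_merge(
    hits_per_pipeline: Mapping[str, set[str]], min_pipelines: int = 2
) -> set[str]:
    """Genes flagged as hits by at least ``min_pipelines`` pipelines."""
    if not hits_per_pipeline:
        raise ValueError("need at least one pipeline result")
    tally: dict[str, int] = {}
    for hits in hits_per_pipeline.values():
        for g in hits:
            tally[g] = tally.get(g, 0) + 1
    return {g for g, n in tally.items() if n >= min_pipelines}


class QuartileResult(NamedTuple):
    passed: bool
    reason: str
    q3_mut_final: float
    q1_wt_day1: float
    q1_wt_final: float


def quartile_separation_filter(
    zscores: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    library: SgRNALibrary,
) -> QuartileResult:
    """Strict quartile separation of a gene's sgRNA Z-scores.

    Pass iff Q3 over the mutant final-day samples is strictly below Q1 over
    the WT day-1 samples *and* below Q1 over the WT final-day samples.
    Quartiles use linear interpolation between order statistics ("type 7").
    Fewer than two observations in any group fails with a recorded reason.
    """
    ids = library.gene_map().get(gene, [])
    ids = [i for i in ids if i in zscores.index]
    wt_days = samples.loc[samples["background"] == "WT", "day"]
    mut_days = samples.loc[samples["background"] == "MUT", "day"]

    def group_cols(background: str, day: int) -> list[str]:
        sel = samples[(samples["background"] == background) & (samples["day"] == day)]
        return [s for s in sel["sample_id"] if s in zscores.columns]

    groups = {
        "MUT_final": group_cols("MUT", int(mut_days.max())),
        "WT_day1": group_cols("WT", int(wt_days.min())),
        "WT_final": group_cols("WT", int(wt_days.max())),
    }
    values = {}
    for name, cols in groups.items():
        vals = zscores.loc[ids, cols].to_numpy().ravel() if ids and cols else np.array([])
        if len(vals) < 2:
            return QuartileResult(
                False, f"<2 sgRNA observations in {name}", np.nan, np.nan, np.nan
            )
        values[name] = vals

    q3_mut = float(np.percentile(values["MUT_final"], 75))
    q1_wt0 = float(np.percentile(values["WT_day1"], 25))
    q1_wt1 = float(np.percentile(values["WT_final"], 25))
    passed = q3_mut < q1_wt0 and q3_mut < q1_wt1
    return QuartileResult(passed, "" if passed else "no separation", q3_mut, q1_wt0, q1_wt1)


class HitCallResult(NamedTuple):
    hits: pd.DataFrame  # final candidates (post-quartile)
    pre_quartile: pd.DataFrame  # trend-consensus survivors before the quartile filter
    scores: pd.DataFrame  # full long-format score table with classes


def call_hits(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    library: SgRNALibrary,
    expression: pd.DataFrame,
    config: HitCallConfig = HitCallConfig(),
    comparisons: Sequence[ComparisonSpec] | None = None,
    pipelines: Sequence[str] = ("A", "B", "C"),
    pseudocount: float = 0.5,
    n_perm: int = 1000,
    seed: int = 0,
) -> HitCallResult:
    """Run the full cascade and return the surviving candidates.

    Stages: normalisation -> CS -> significance per pipeline -> BH
    adjustment -> class assignment -> expression filter -> trend selection
    -> pipeline consensus -> quartile-separation filter.  The quartile
    filter is evaluated only for trend-consensus survivors (cheaper, same
    result), on Z-scores of fraction-normalised abundances.
    """
    if comparisons is None:
        comparisons = default_comparisons(samples)
    scores = run_pipelines(
        counts,
        samples,
        library,
        comparisons=comparisons,
        pipelines=pipelines,
        pseudocount=pseudocount,
        n_perm=n_perm,
        seed=seed,
    )
    scores = classify_scores(scores, config)

    expressed = set(
        expression_filter(
            sorted(scores["gene"].unique()), expression, config.expression_threshold
        )
    )
    kept = scores[scores["gene"].isin(expressed)]

    trend_by_pipeline: dict[str, pd.DataFrame] = {}
    for pipe, sub in kept.groupby("pipeline"):
        trend_by_pipeline[pipe] = select_trend_hits(sub).set_index("gene")
    hit_sets = {
        pipe: set(df.index[df["hit"]]) for pipe, df in trend_by_pipeline.items()
    }
    consensus = consensus_merge(hit_sets, config.min_pipelines)

    mut_star = kept[kept["comparison"] == "MUT_star"]
    rows = []
    for gene in sorted(consensus):
        n_pipes = sum(gene in hits for hits in hit_sets.values())
        trends = [
            int(df.loc[gene, "trend"])
            for df in trend_by_pipeline.values()
            if gene in df.index and df.loc[gene, "hit"]
        ]
        sub = mut_star[mut_star["gene"] == gene]
        rows.append(
            (
                gene,
                min(trends),
                n_pipes,
                float(sub["cs"].mean()),
                float(sub["p_adj"].min()),
            )
        )
    pre_quartile = pd.DataFrame(
        rows, columns=["gene", "trend", "n_pipelines", "cs_MUTstar", "p_adj_MUTstar"]
    )

    if config.quartile_filter and len(pre_quartile):
        z, _ = sgrna_zscores(normalize_counts(counts, "fraction", library))
        qpass = [
            quartile_separation_filter(z, samples, g, library).passed
            for g in pre_quartile["gene"]
        ]
        pre_quartile = pre_quartile.assign(quartile_pass=qpass)
        hits = pre_quartile[pre_quartile["quartile_pass"]].reset_index(drop=True)
    else:
        pre_quartile = pre_quartile.assign(quartile_pass=True)
        hits = pre_quartile.copy()
    return HitCallResult(hits, pre_quartile, scores)
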