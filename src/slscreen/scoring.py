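"""Normalisation and gene-level scoring of pooled CRISPR screens.

The gene-level statistic is the CRISPR score (CS): the unweighted mean over
a gene's sgRNAs of log2(abundance in condition 1 / abundance in condition 2),
with replicate samples averaged per side and a pseudocount guarding zeros.
A negative CS means the gene's guides dropped out between the two conditions.

Three scoring pipelines share the CS definition but differ in normalisation
and in the significance test attached to the per-sgRNA log-ratio
distribution:

====  ==============  ====================================================
id    normalisation   per-gene significance test
====  ==============  ====================================================
A     rpm             one-sample two-sided t-test of log-ratios against 0
B     median_ratio    two-sided rank-sum vs the non-targeting guides
C     control_scaled  permutation of random same-size sgRNA sets
====  ==============  ====================================================

Spanning a parametric, a rank-based and a resampling null is what makes the
downstream >=2-of-3 consensus meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import SgRNALibrary

NORMALIZATION_METHODS = ("fraction", "rpm", "median_ratio", "control_scaled")
PIPELINES = ("A", "B", "C")
COMPARISONS = ("WT", "MUT", "MUT_star")

#: normalisation method used by each pipeline
PIPELINE_NORMALIZATION: Mapping[str, str] = {
    "A": "rpm",
    "B": "median_ratio",
    "C": "control_scaled",
}

P_FLOOR = 1e-12  # reported p for degenerate zero-variance tests


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "background", "day", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    if (df < 0).any().any():
        raise ValueError("count matrix contains negative values")
    return df


@dataclass(frozen=True)
class ComparisonSpec:
    """One of the study's three condition contrasts.

    ``WT``: WT final day vs WT day 1 — fitness cost of a knockout in the
    wild-type background.  ``MUT``: mutant final day vs WT day 1 — cost in
    the mutant background, against the shared baseline.  ``MUT_star``:
    mutant final day vs WT final day — the differential (synthetic-lethal)
    contrast.
    """

    name: str
    numerator: tuple[str, ...]  # condition-1 sample ids
    denominator: tuple[str, ...]  # condition-2 sample ids

    def __post_init__(self) -> None:
        if self.name not in COMPARISONS:
            raise ValueError(f"unknown comparison name {self.name!r}")
        if not self.numerator or not self.denominator:
            raise ValueError(f"comparison {self.name}: empty sample list")

    def swapped(self) -> "ComparisonSpec":
        return ComparisonSpec(self.name, self.denominator, self.numerator)


def default_comparisons(samples: pd.DataFrame) -> list[ComparisonSpec]:
    """Build the WT / MUT / MUT_star contrasts from a sample sheet.

    Final day per background = its largest day; WT day 1 (the background's
    smallest day) is the shared baseline of both the WT and MUT contrasts.
    """

    def ids(background: str, day: int) -> tuple[str, ...]:
        sel = samples[(samples["background"] == background) & (samples["day"] == day)]
        return tuple(sel["sample_id"])

    wt_days = samples.loc[samples["background"] == "WT", "day"]
    mut_days = samples.loc[samples["background"] == "MUT", "day"]
    if wt_days.empty or mut_days.empty:
        raise ValueError("sample sheet must contain both WT and MUT backgrounds")
    wt0, wt1 = int(wt_days.min()), int(wt_days.max())
    mut1 = int(mut_days.max())
    return [
        ComparisonSpec("WT", ids("WT", wt1), ids("WT", wt0)),
        ComparisonSpec("MUT", ids("MUT", mut1), ids("WT", wt0)),
        ComparisonSpec("MUT_star", ids("MUT", mut1), ids("WT", wt1)),
    ]


# ---------------------------------------------------------------------------
# normalisation


def normalize_counts(
    matrix: pd.DataFrame,
    method: str = "fraction",
    library: SgRNALibrary | None = None,
) -> pd.DataFrame:
    """Per-sample normalisation of an sgRNA count matrix.

    fraction        count / column total
    rpm             fraction * 1e6 (reads per million)
    median_ratio    count / size factor, size factor = median over sgRNAs of
                    count / geometric mean across samples (rows containing a
                    zero are excluded from the median)
    control_scaled  count / total of non-targeting counts in the sample
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalisation method {method!r}")
    if matrix.size == 0:
        raise ValueError("empty count matrix")
    totals = matrix.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {list(dead.index)}")

    if method == "fraction":
        return matrix / totals
    if method == "rpm":
        return matrix / totals * 1e6
    if method == "median_ratio":
        vals = matrix.to_numpy(dtype=float)
        positive = (vals > 0).all(axis=1)
        if not positive.any():
            raise ValueError("median_ratio: every sgRNA has a zero count somewhere")
        ref = np.exp(np.mean(np.log(vals[positive]), axis=1))
        factors = np.median(vals[positive] / ref[:, None], axis=0)
        return matrix / factors
    # control_scaled
    if library is None:
        raise ValueError("control_scaled normalisation requires the library")
    nt = [i for i in library.nontargeting_ids() if i in matrix.index]
    if not nt:
        raise ValueError("control_scaled requires >=1 non-targeting sgRNA in the matrix")
    factors = matrix.loc[nt].sum(axis=0)
    if (factors <= 0).any():
        raise ValueError("control_scaled: zero non-targeting total in a sample")
    return matrix / factors


def sgrna_zscores(normalized: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sgRNA Z-score across all samples: (x - row mean) / row sd (ddof=1).

    Rows with zero variance get Z=0 and are flagged.  Requires >=2 samples.
    """
    if normalized.shape[1] < 2:
        raise ValueError("Z-scores require at least two samples")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    flat = sd == 0
    sd_safe = sd.mask(flat, 1.0)
    z = normalized.sub(mean, axis=0).div(sd_safe, axis=0)
    z[flat] = 0.0
    return z, flat.rename("zero_variance")


# ---------------------------------------------------------------------------
# CRISPR score


class CrisprScores(NamedTuple):
    gene_scores: pd.DataFrame  # gene, cs, n_sgrnas
    sgrna_logratios: pd.Series  # per-sgRNA log2 ratio, index sgrna_id
    sgrna_gene: pd.Series  # sgrna_id -> gene ('' for non-targeting)


def gene_crispr_score(
    normalized: pd.DataFrame,
    comparison: ComparisonSpec,
    library: SgRNALibrary,
    pseudocount: float = 0.5,
) -> CrisprScores:
    """CRISPR score per gene for one comparison.

    Abundances are averaged over each side's replicate samples, brought to a
    common reads-per-million-like scale by one global factor (so the
    pseudocount has the same weight whichever normalisation produced the
    table), then log2(cond1/cond2) is taken per sgRNA and averaged per gene.
    Per-sgRNA log-ratios are retained for the significance tests; genes with
    no sgRNAs in the matrix are omitted.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for side in (comparison.numerator, comparison.denominator):
        missing = [s for s in side if s not in normalized.columns]
        if missing:
            raise ValueError(f"comparison {comparison.name}: missing samples {missing}")

    # one global scalar preserves all cross-sample ratios but fixes the units
    target_mean = 1e6 / len(normalized)
    scale = target_mean / normalized.to_numpy().mean()
    table = normalized * scale

    num = table[list(comparison.numerator)].mean(axis=1) + pseudocount
    den = table[list(comparison.denominator)].mean(axis=1) + pseudocount
    logratios = np.log2(num / den)

    gene_of = pd.Series(
        {r.sgrna_id: r.target_gene for r in library.records}, name="gene"
    ).reindex(logratios.index, fill_value="")
    targeted = gene_of != ""
    grouped = logratios[targeted].groupby(gene_of[targeted])
    gene_scores = grouped.agg(cs="mean", n_sgrnas="size").reset_index(names="gene")
    absent = set(library.genes) - set(gene_scores["gene"])
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) have no sgRNAs in the count matrix and were omitted",
            stacklevel=2,
        )
    return CrisprScores(gene_scores, logratios, gene_of)


# ---------------------------------------------------------------------------
# significance tests


def _ttest_by_gene(logratios: pd.Series, gene_of: pd.Series) -> pd.Series:
    pvals = {}
    for gene, vals in logratios[gene_of != ""].groupby(gene_of[gene_of != ""]):
        x = vals.to_numpy()
        if len(x) < 2:
            raise ValueError(f"t-test requires >=2 sgRNAs (gene {gene!r})")
        if np.ptp(x) == 0:
            pvals[gene] = P_FLOOR
            continue
        pvals[gene] = float(stats.ttest_1samp(x, 0.0).pvalue)
    return pd.Series(pvals, name="p")


def _ranksum_by_gene(
    logratios: pd.Series, gene_of: pd.Series, library: SgRNALibrary
) -> pd.Series:
    nt = [i for i in library.nontargeting_ids() if i in logratios.index]
    if not nt:
        raise ValueError("rank-sum test requires non-targeting sgRNAs")
    ref = logratios.loc[nt].to_numpy()
    pvals = {}
    for gene, vals in logratios[gene_of != ""].groupby(gene_of[gene_of != ""]):
        res = stats.mannwhitneyu(
            vals.to_numpy(), ref, alternative="two-sided", method="asymptotic"
        )
        pvals[gene] = float(res.pvalue)
    return pd.Series(pvals, name="p")


def _permutation_by_gene(
    logratios: pd.Series,
    gene_of: pd.Series,
    n_perm: int,
    seed: int,
) -> pd.Series:
    if n_perm < 100:
        raise ValueError("permutation test requires n_perm >= 100")
    rng = np.random.default_rng(seed)
    pool = logratios.to_numpy()
    obs = logratios[gene_of != ""].groupby(gene_of[gene_of != ""]).agg(["mean", "size"])
    pvals = {}
    # one shared null per gene-set size: random sgRNA sets drawn from all sgRNAs
    for size, sub in obs.groupby("size"):
        idx = rng.integers(0, len(pool), size=(n_perm, int(size)))
        null_abs = np.sort(np.abs(pool[idx].mean(axis=1)))
        n_ge = n_perm - np.searchsorted(null_abs, np.abs(sub["mean"].to_numpy()), side="left")
        p = (1.0 + n_ge) / (1.0 + n_perm)
        pvals.update(zip(sub.index, p))
    return pd.Series(pvals, name="p")


def significance_test(
    scores: CrisprScores,
    pipeline_id: str,
    library: SgRNALibrary,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene p-value from the sgRNA log-ratio distribution.

    Pipeline A: one-sample two-sided t-test of the gene's log-ratios vs 0
    (zero-variance input is reported at the floor ``P_FLOOR``).
    Pipeline B: two-sided Wilcoxon rank-sum of the gene's log-ratios vs the
    non-targeting controls.  Pipeline C: permutation test with the add-one
    estimator p = (1 + #{|CS_null| >= |CS_obs|}) / (1 + n_perm), null CS
    from random same-size sgRNA sets drawn from all sgRNAs.
    """
    if pipeline_id == "A":
        return _ttest_by_gene(scores.sgrna_logratios, scores.sgrna_gene)
    if pipeline_id == "B":
        return _ranksum_by_gene(scores.sgrna_logratios, scores.sgrna_gene, library)
    if pipeline_id == "C":
        return _permutation_by_gene(scores.sgrna_logratios, scores.sgrna_gene, n_perm, seed)
    raise ValueError(f"unknown pipeline {pipeline_id!r}")


def adjust_pvalues(pvalues: Iterable[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (default) step-up adjustment, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# full multi-pipeline scoring


def run_pipelines(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    library: SgRNALibrary,
    comparisons: Sequence[ComparisonSpec] | None = None,
    pipelines: Sequence[str] = PIPELINES,
    pseudocount: float = 0.5,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every gene under every pipeline and comparison.

    Returns a long-format frame ``gene comparison pipeline cs p p_adj
    n_sgrnas``; adjustment is Benjamini–Hochberg within each
    (comparison, pipeline) family.
    """
    if comparisons is None:
        comparisons = default_comparisons(samples)
    out = []
    for pipe in pipelines:
        normalized = normalize_counts(counts, PIPELINE_NORMALIZATION[pipe], library)
        for comp in comparisons:
            scores = gene_crispr_score(normalized, comp, library, pseudocount)
            p = significance_test(scores, pipe, library, n_perm=n_perm, seed=seed)
            df = scores.gene_scores.merge(
                p.rename("p"), left_on="gene", right_index=True
            )
            df["p_adj"] = adjust_pvalues(df["p"])
            df["comparison"] = comp.name
            df["pipeline"] = pipe
            out.append(df)
    result = pd.concat(out, ignore_index=True)
    return result[["gene", "comparison", "pipeline", "cs", "p", "p_adj", "n_sgrnas"]]


# ---------------------------------------------------------------------------
# spacer counting from reads


def count_spacers(
    fastq_paths: Sequence[str] | str,
    library: SgRNALibrary,
) -> tuple[pd.Series, dict[str, int]]:
    """Count exact spacer matches (either strand) in FASTQ read files.

    Each read is scanned for 20-mers matching a library spacer or its
    reverse complement; reads matching more than one distinct sgRNA are
    discarded and tallied as ambiguous.  Returns one count-matrix column
    (indexed like the library) plus a QC tally.
    """
    from Bio import SeqIO
    from Bio.Seq import reverse_complement

    if isinstance(fastq_paths, str):
        fastq_paths = [fastq_paths]
    lookup: dict[str, str] = {}
    for rec in library.records:
        lookup[rec.spacer] = rec.sgrna_id
        lookup[reverse_complement(rec.spacer)] = rec.sgrna_id

    counts = pd.Series(0, index=pd.Index(library.sgrna_ids, name="sgrna_id"))
    qc = {"reads": 0, "matched": 0, "ambiguous": 0, "unmatched": 0}
    for path in fastq_paths:
        for read in SeqIO.parse(path, "fastq"):
            qc["reads"] += 1
            seq = str(read.seq).upper()
            hits = {
                lookup[seq[i : i + 20]]
                for i in range(len(seq) - 19)
                if seq[i : i + 20] in lookup
            }
            if len(hits) == 1:
                counts[hits.pop()] += 1
                qc["matched"] += 1
            elif len(hits) > 1:
                qc["ambiguous"] += 1
            else:
                qc["unmatched"] += 1
    return counts, qc
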