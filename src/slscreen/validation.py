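"""Validation-assay statistics.

Two readouts validate screen candidates orthogonally to the screens
themselves: FACS-monitored cell-competition time series (does knocking out
the candidate selectively deplete mutant cells from a mixed culture?), and
public drug-sensitivity panels over cancer cell lines grouped by
mismatch-repair (MMR) or TP53 status (are annotated-deficient lines more
sensitive to an inhibitor of the candidate?).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def normalize_competition(series: pd.DataFrame) -> pd.DataFrame:
    """Normalise each replicate's KO-fraction path to its first time point.

    Input is tidy (``day replicate condition fraction_ko``); output replaces
    ``fraction_ko`` with the fold change relative to the replicate's earliest
    day.  Replicates with a zero initial fraction are excluded with a warning.
    """
    out = []
    for (cond, rep), sub in series.groupby(["condition", "replicate"]):
        sub = sub.sort_values("day")
        f0 = sub["fraction_ko"].iloc[0]
        if f0 <= 0:
            warnings.warn(
                f"replicate {rep} ({cond}): zero initial fraction, excluded",
                stacklevel=2,
            )
            continue
        norm = sub.copy()
        norm["fraction_ko"] = sub["fraction_ko"] / f0
        out.append(norm)
    if not out:
        raise ValueError("no replicate has a positive initial fraction")
    return pd.concat(out, ignore_index=True)


def competition_test(
    control: Sequence[float],
    treated: Sequence[float],
    direction: str = "less",
) -> float:
    """One-sided two-sample t-test at a single time point.

    ``direction='less'`` tests whether treated values (mutant-cell
    abundance under candidate knockout/inhibition) are lower than control.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >=2 values per group")
    if np.ptp(control) == 0 and np.ptp(treated) == 0:
        raise ValueError("degenerate (zero-variance) values in both groups")
    res = stats.ttest_ind(treated, control, alternative=direction)
    return float(res.pvalue)


def competition_table(
    series: pd.DataFrame, direction: str = "less"
) -> pd.DataFrame:
    """Per-time-point one-sided test of treated vs control fractions."""
    rows = []
    for day, sub in series.groupby("day"):
        ctrl = sub.loc[sub["condition"] == "control", "fraction_ko"]
        trt = sub.loc[sub["condition"] == "treated", "fraction_ko"]
        if len(ctrl) < 2 or len(trt) < 2:
            continue
        if np.ptp(ctrl) == 0 and np.ptp(trt) == 0:
            # e.g. the normalisation anchor day, where every value is 1
            p = float("nan")
        else:
            p = competition_test(ctrl, trt, direction)
        rows.append((day, float(ctrl.mean()), float(trt.mean()), p))
    return pd.DataFrame(rows, columns=["day", "mean_control", "mean_treated", "p"])


class MmrGroups(NamedTuple):
    deficient: pd.DataFrame
    proficient: pd.DataFrame
    excluded: pd.DataFrame


def group_ccls_by_mmr(records: pd.DataFrame) -> MmrGroups:
    """Partition cell lines by mismatch-repair status.

    Deficient = microsatellite-instable (MSI) *and* carrying an MMR-gene
    mutation; proficient = microsatellite-stable (MSS) *and* without one;
    everything else (including missing annotations) is excluded.
    """
    required = {"msi_status", "mmr_mutated"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records lack columns {sorted(missing_cols)}")
    annotated = records.dropna(subset=list(required))
    if len(annotated) < len(records):
        warnings.warn(
            f"{len(records) - len(annotated)} record(s) with missing "
            "annotations were excluded",
            stacklevel=2,
        )
    deficient = annotated[
        (annotated["msi_status"] == "MSI") & annotated["mmr_mutated"].astype(bool)
    ]
    proficient = annotated[
        (annotated["msi_status"] == "MSS") & ~annotated["mmr_mutated"].astype(bool)
    ]
    kept = set(deficient.index) | set(proficient.index)
    excluded = records.loc[[i for i in records.index if i not in kept]]
    return MmrGroups(deficient, proficient, excluded)


def group_ccls_by_tp53(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cell lines into TP53 loss-of-function vs TP53 wild-type."""
    lof = records["tp53_lof"].astype(bool)
    return records[lof], records[~lof]


class KSResult(NamedTuple):
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_sensitivity(
    group_a: Sequence[float], group_b: Sequence[float]
) -> KSResult:
    """Two-sample two-sided Kolmogorov–Smirnov test of sensitivity values.

    The exact null distribution is used when both groups have n <= 25,
    the asymptotic one otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    method = "exact" if max(len(a), len(b)) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(
        float(res.statistic), float(res.pvalue), float(np.median(a)), float(np.median(b))
    )
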