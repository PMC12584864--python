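"""Amplicon allele tracking in haploid cells.

In a haploid background every amplicon read is one allele of one cell
lineage, so per-allele read frequencies are direct lineage frequencies.
This module classifies editing outcomes by reading frame (frameshift FS,
non-frameshift NFS, or unedited/WT), references indel locations to the
Cas9 cut site (position 0, ~3 bp 5' of the PAM), quality-controls cut-site
clustering, converts counts to frequencies, normalises per-allele
trajectories to the first time point, and tests WT-vs-KO trend differences.

Allele descriptor grammar (one allele = semicolon-joined events, or "WT"):

    D:<start>:<length>     deletion of <length> bp starting at <start>
    I:<start>:<seq>        insertion of <seq> at <start>
    S:<start>:<seq>        substitution of <seq> starting at <start>

Positions are signed integers relative to the cut site.  Substitutions
carry no frame consequence and an allele with only substitutions is
classed WT for frame purposes (a nonsense substitution would be LoF
biologically, but that is not derivable from indel arithmetic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EVENT_KINDS = ("insertion", "deletion", "substitution")


@dataclass(frozen=True)
class IndelEvent:
    """One editing event at a signed position relative to the cut site."""

    kind: str
    start: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind in ("insertion", "substitution"):
            if len(self.inserted_seq) != self.length:
                raise ValueError(
                    f"{self.kind} sequence length {len(self.inserted_seq)} "
                    f"!= declared length {self.length}"
                )

    @property
    def signed_length(self) -> int:
        """Net change in allele length: + for insertions, - for deletions."""
        if self.kind == "insertion":
            return self.length
        if self.kind == "deletion":
            return -self.length
        return 0

    @property
    def affected_positions(self) -> range:
        """Reference positions touched by the event (insertion: one position)."""
        if self.kind == "insertion":
            return range(self.start, self.start + 1)
        return range(self.start, self.start + self.length)


def classify_allele(events: Sequence[IndelEvent]) -> str:
    """FS/NFS/WT frame classification from indel arithmetic.

    No insertion or deletion events -> "WT"; otherwise the net indel length
    decides: divisible by 3 -> "NFS", else "FS".
    """
    net = sum(e.signed_length for e in events if e.kind != "substitution")
    has_indel = any(e.kind != "substitution" for e in events)
    if not has_indel:
        return "WT"
    return "FS" if net % 3 != 0 else "NFS"


def allele_location(events: Sequence[IndelEvent]) -> int:
    """Signed location of an allele: the affected position nearest the cut site.

    Multi-position events contribute all their positions; ties in |position|
    break toward the negative (PAM-distal) side.  Raises on an empty event
    list — the unedited allele has no location.
    """
    events = list(events)
    if not events:
        raise ValueError("WT allele has no location")
    positions = [p for e in events for p in e.affected_positions]
    return min(positions, key=lambda p: (abs(p), p))


@dataclass(frozen=True)
class AlleleDescriptor:
    """Parsed allele: events plus derived net length and frame class."""

    events: tuple[IndelEvent, ...]
    net_length: int = field(init=False)
    frame_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "net_length", sum(e.signed_length for e in self.events)
        )
        object.__setattr__(self, "frame_class", classify_allele(self.events))

    def __str__(self) -> str:
        return format_descriptor(self.events)


def format_descriptor(events: Sequence[IndelEvent]) -> str:
    if not events:
        return "WT"
    parts = []
    for e in events:
        if e.kind == "deletion":
            parts.append(f"D:{e.start}:{e.length}")
        elif e.kind == "insertion":
            parts.append(f"I:{e.start}:{e.inserted_seq}")
        else:
            parts.append(f"S:{e.start}:{e.inserted_seq}")
    return ";".join(parts)


def parse_descriptor(text: str) -> AlleleDescriptor:
    """Parse a descriptor string; malformed tokens raise with the token named."""
    text = text.strip()
    if text == "WT":
        return AlleleDescriptor(())
    events = []
    for token in text.split(";"):
        fields = token.split(":")
        if len(fields) != 3:
            raise ValueError(f"malformed allele token {token!r}")
        tag, start_s, payload = fields
        try:
            start = int(start_s)
        except ValueError:
            raise ValueError(f"malformed allele token {token!r}: bad position") from None
        if tag == "D":
            try:
                length = int(payload)
            except ValueError:
                raise ValueError(f"malformed allele token {token!r}: bad length") from None
            events.append(IndelEvent("deletion", start, length))
        elif tag == "I":
            events.append(IndelEvent("insertion", start, len(payload), payload))
        elif tag == "S":
            events.append(IndelEvent("substitution", start, len(payload), payload))
        else:
            raise ValueError(f"malformed allele token {token!r}: unknown tag {tag!r}")
    return AlleleDescriptor(tuple(events))


# ---------------------------------------------------------------------------
# tables, frequencies, trajectories


def parse_allele_table(path_or_frame) -> pd.DataFrame:
    """Load a tidy allele table (``allele  sample_id  count``) into a
    wide count matrix (rows = allele descriptor string, columns = samples).

    Every descriptor is validated through the grammar on the way in.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        tidy = path_or_frame
    else:
        tidy = pd.read_csv(path_or_frame, sep="\t", dtype={"allele": str})
    missing = {"allele", "sample_id", "count"} - set(tidy.columns)
    if missing:
        raise ValueError(f"allele table lacks columns {sorted(missing)}")
    for desc in tidy["allele"].unique():
        parse_descriptor(desc)
    wide = tidy.pivot_table(
        index="allele", columns="sample_id", values="count", aggfunc="sum", fill_value=0
    )
    wide.columns.name = None
    return wide


def allele_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative frequencies (columns sum to 1)."""
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return table / totals


def cutsite_clustering_qc(
    table: pd.DataFrame, window: int = 5
) -> dict[str, float]:
    """Fraction of mutations within ``window`` bp of the cut site.

    Reported both read-weighted (each read one haploid cell) and at the
    allele level (each distinct mutant allele once).  The unedited allele
    is not a mutation and is excluded.  With no mutant alleles both
    fractions are NaN.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    mutant = [a for a in table.index if a != "WT"]
    if not mutant:
        return {"read_weighted": float("nan"), "allele_level": float("nan")}
    locs = np.array(
        [allele_location(parse_descriptor(a).events) for a in mutant]
    )
    near = np.abs(locs) <= window
    reads = table.loc[mutant].sum(axis=1).to_numpy(dtype=float)
    return {
        "read_weighted": float(reads[near].sum() / reads.sum()),
        "allele_level": float(near.mean()),
    }


class Trajectories(NamedTuple):
    fold_change: pd.DataFrame  # rows (allele, group), columns = days, tp1 == 1
    excluded: list[str]  # alleles dropped for absence at tp1


def normalize_trajectories(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    groups: Sequence[str] = ("WT", "KO"),
    frame_classes: Sequence[str] = ("FS",),
) -> Trajectories:
    """Per-allele fold-change trajectories relative to the first time point.

    Restricted to loss-of-function (default: frameshift) alleles present at
    the first time point in *both* groups; within a group, fold changes are
    computed per replicate (freq_t / freq_tp1) and then averaged across
    replicates.  Alleles absent at tp1 anywhere are excluded and reported.
    """
    days = sorted(samples["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two time points")
    day0 = days[0]
    freqs = allele_frequencies(table)

    keep = [
        a
        for a in table.index
        if a != "WT" and parse_descriptor(a).frame_class in frame_classes
    ]
    by_group_rep: dict[tuple[str, int], pd.DataFrame] = {}
    for (bg, rep), sub in samples.groupby(["background", "replicate"]):
        if bg not in groups:
            continue
        cols = sub.sort_values("day")["sample_id"].tolist()
        day_order = sub.sort_values("day")["day"].tolist()
        f = freqs.loc[keep, cols]
        f.columns = day_order
        by_group_rep[(bg, rep)] = f

    excluded = []
    retained = []
    for a in keep:
        if all(f.loc[a, day0] > 0 for f in by_group_rep.values()):
            retained.append(a)
        else:
            excluded.append(a)

    rows = {}
    for g in groups:
        reps = [f for (bg, _), f in by_group_rep.items() if bg == g]
        if not reps:
            raise ValueError(f"no samples for group {g!r}")
        for a in retained:
            fc = np.mean(
                [f.loc[a].to_numpy() / f.loc[a, day0] for f in reps], axis=0
            )
            rows[(a, g)] = fc
    fold = pd.DataFrame.from_dict(rows, orient="index", columns=days)
    fold.index = pd.MultiIndex.from_tuples(rows.keys(), names=["allele", "group"])
    return Trajectories(fold, excluded)


def top_alleles(
    table: pd.DataFrame, k: int, frame_classes: Sequence[str] = ("FS",)
) -> list[str]:
    """The k loss-of-function alleles with the largest cumulative frequency
    across all samples; ties break by descriptor string order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = allele_frequencies(table)
    lof = [
        a
        for a in table.index
        if a != "WT" and parse_descriptor(a).frame_class in frame_classes
    ]
    if k > len(lof):
        warnings.warn(
            f"requested top {k} alleles but only {len(lof)} available", stacklevel=2
        )
    cumulative = freqs.loc[lof].sum(axis=1)
    ranked = sorted(lof, key=lambda a: (-cumulative[a], a))
    return ranked[:k]


class TrendTestResult(NamedTuple):
    statistic: float
    pvalue: float
    mean_wt: float
    mean_ko: float
    n_alleles: int


def group_trend_test(
    trajectories: pd.DataFrame,
    timepoint: int,
    groups: tuple[str, str] = ("WT", "KO"),
    equal_var: bool = False,
    paired: bool = False,
) -> TrendTestResult:
    """Two-sided t-test of per-allele fold changes at ``timepoint``, WT vs KO.

    Welch by default (``equal_var=False``); ``paired=True`` pairs the two
    groups by allele, which is available because the trajectory set is
    restricted to alleles shared at tp1.
    """
    wt = trajectories.xs(groups[0], level="group")[timepoint].to_numpy()
    ko = trajectories.xs(groups[1], level="group")[timepoint].to_numpy()
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("need at least two alleles per group")
    if np.ptp(wt) == 0 and np.ptp(ko) == 0:
        raise ValueError("degenerate (zero-variance) fold changes in both groups")
    if paired:
        res = stats.ttest_rel(wt, ko)
    else:
        res = stats.ttest_ind(wt, ko, equal_var=equal_var)
    return TrendTestResult(
        float(res.statistic), float(res.pvalue), float(wt.mean()), float(ko.mean()), len(wt)
    )
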