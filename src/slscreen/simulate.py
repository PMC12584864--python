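"""Synthetic-data generators with known ground truth.

These emulate the data-generating processes of a paired-background
synthetic-lethality study in haploid cells:

* pooled CRISPR dropout screens run in a wild-type (WT) and a mutant (MUT)
  background, sampled at several days and sequenced to a target depth —
  exponential per-guide selection with negative-binomial count noise;
* amplicon sequencing of a single Cas9-edited locus over time, where each
  read is one haploid allele — indels clustered geometrically around the
  cut site, under frame-class- and background-dependent selection;
* two-population cell-competition assays read out by FACS;
* drug-sensitivity panels over cell lines annotated with MSI/MMR/TP53 status.

Every generator is deterministic given its seed and returns the planted
truth alongside the observable tables, so downstream hit calling and
trajectory statistics can be benchmarked for recall, precision and
error-rate calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .alleles import IndelEvent, classify_allele, format_descriptor
from .library import SgRNALibrary

GENE_CLASSES = ("neutral", "essential", "sl_mutant_only", "wt_advantage")


@dataclass(frozen=True)
class GeneEffectSpec:
    """Planted per-gene fitness effect.

    ``s_wt`` / ``s_mut`` are per-day log-fitness coefficients in the WT and
    mutant backgrounds; a cell carrying a knockout of the gene changes
    abundance as exp(s*t).  The class label is redundant with the signs but
    kept as ground truth for benchmarking.
    """

    gene: str
    class_label: str
    s_wt: float = 0.0
    s_mut: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in GENE_CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        ok = {
            "neutral": self.s_wt == 0 and self.s_mut == 0,
            "essential": self.s_wt < 0 and self.s_mut < 0,
            "sl_mutant_only": self.s_mut < 0 and self.s_wt >= 0,
            "wt_advantage": self.s_wt > 0,
        }[self.class_label]
        if not ok:
            raise ValueError(
                f"fitness ({self.s_wt}, {self.s_mut}) inconsistent with "
                f"class {self.class_label!r} for gene {self.gene!r}"
            )


@dataclass
class ScreenSimConfig:
    """Parameters of a simulated paired-background dropout screen.

    Defaults mirror a desk-scale version of a genome-wide screen: five
    time points per background, the WT arm harvested at day 21 and the
    mutant arm at day 27, duplicate samples, and sequencing depth expressed
    as expected total reads per sample.  ``dispersion`` is the
    negative-binomial size parameter (var = m + m^2/size).
    """

    library: SgRNALibrary
    effects: Mapping[str, GeneEffectSpec]
    days: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"WT": (1, 6, 11, 16, 21), "MUT": (1, 7, 14, 20, 27)}
    )
    replicates: int = 2
    depth: float = 2_000_000.0
    dispersion: float = 10.0
    sgrna_efficiency_range: tuple[float, float] = (0.7, 1.0)
    lib_sigma: float = 0.3
    unexpressed_genes: Sequence[str] = ()
    expression_value: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for bg, days in self.days.items():
            d = list(days)
            if d != sorted(d) or len(set(d)) != len(d):
                raise ValueError(f"days for {bg} must be strictly increasing: {d}")
        if self.depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth and dispersion must be positive")
        lo, hi = self.sgrna_efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("sgrna_efficiency_range must lie in (0, 1]")
        missing = [
            g
            for g in self.library.genes
            if g not in self.effects
        ]
        # genes without an explicit effect are treated as neutral
        self._implicit_neutral = set(missing)


class ScreenSim(NamedTuple):
    counts: pd.DataFrame  # sgrna_id x sample_id, integer reads
    samples: pd.DataFrame  # sample_id, background, day, replicate
    expression: pd.DataFrame  # gene, expression
    truth: pd.DataFrame  # gene, class_label, s_wt, s_mut


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # numpy parameterisation: n = size, p = size / (size + mean)
    mean = np.clip(mean, 1e-12, None)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_screen_counts(config: ScreenSimConfig) -> ScreenSim:
    """Simulate an sgRNA count time course for each configured background.

    The expected read fraction of sgRNA *i* (gene *g*, efficiency ``u_i``,
    initial abundance ``a_i``) in background *b* at day *t* is proportional
    to ``a_i * exp(u_i * s_{g,b} * t)``; counts are negative-binomial with
    mean fraction*depth.  Non-targeting guides and genes without a planted
    effect evolve neutrally (s = 0).
    """
    lib = config.library
    rng = np.random.default_rng(config.seed)
    n = len(lib)
    if n == 0:
        raise ValueError("cannot simulate from an empty library")

    for spec in config.effects.values():
        if spec.gene not in set(lib.genes):
            raise ValueError(f"effect specified for gene {spec.gene!r} not in library")
    for bg in config.days:
        if bg not in ("WT", "MUT"):
            raise ValueError(f"unknown background {bg!r} (expected WT or MUT)")

    a = rng.lognormal(mean=0.0, sigma=config.lib_sigma, size=n)
    lo, hi = config.sgrna_efficiency_range
    u = rng.uniform(lo, hi, size=n)

    s_by_bg: dict[str, np.ndarray] = {}
    for bg, attr in (("WT", "s_wt"), ("MUT", "s_mut")):
        s = np.zeros(n)
        for i, rec in enumerate(lib.records):
            spec = config.effects.get(rec.target_gene) if rec.target_gene else None
            if spec is not None:
                s[i] = getattr(spec, attr)
        s_by_bg[bg] = s

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for bg, days in config.days.items():
        s = s_by_bg[bg]
        for day in days:
            frac = a * np.exp(u * s * day)
            frac = frac / frac.sum()
            for rep in range(1, config.replicates + 1):
                sid = f"{bg}_d{day}_r{rep}"
                columns[sid] = _nb_draw(rng, frac * config.depth, config.dispersion)
                sample_rows.append((sid, bg, day, rep))

    counts = pd.DataFrame(columns, index=pd.Index(lib.sgrna_ids, name="sgrna_id"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "background", "day", "replicate"]
    )

    unexpressed = set(config.unexpressed_genes)
    genes = lib.genes
    expression = pd.DataFrame(
        {
            "gene": genes,
            "expression": [
                0.0 if g in unexpressed else config.expression_value for g in genes
            ],
        }
    )

    truth_rows = []
    for g in genes:
        spec = config.effects.get(g)
        if spec is None:
            truth_rows.append((g, "neutral", 0.0, 0.0))
        else:
            truth_rows.append((g, spec.class_label, spec.s_wt, spec.s_mut))
    truth = pd.DataFrame(truth_rows, columns=["gene", "class_label", "s_wt", "s_mut"])
    return ScreenSim(counts, samples, expression, truth)


# ---------------------------------------------------------------------------
# amplicon allele time course


@dataclass
class AlleleSimConfig:
    """Parameters of a simulated Cas9 amplicon editing time course.

    ``p_geo`` sets the geometric decay of |indel offset| from the cut site
    (offset 0); ``fitness`` maps (frame class, background) to a per-day
    multiplicative fitness w, so allele frequency follows f_t ∝ f_0 * w^t.
    The unedited allele ("WT" descriptor, fitness 1) is always present.
    """

    n_alleles: int = 138
    p_geo: float = 0.5
    frameshift_fraction: float = 0.7
    fitness: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FS", "WT"): 1.0,
            ("FS", "KO"): 1.0,
            ("NFS", "WT"): 1.0,
            ("NFS", "KO"): 1.0,
        }
    )
    days: Sequence[int] = (0, 7, 14)
    reads_per_sample: int = 50_000
    replicates: int = 2
    backgrounds: Sequence[str] = ("WT", "KO")
    unedited_fraction: float = 0.15
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_geo <= 1:
            raise ValueError("p_geo must be in (0, 1]")
        if any(w <= 0 for w in self.fitness.values()):
            raise ValueError("fitness values must be positive")
        if not 0 <= self.unedited_fraction < 1:
            raise ValueError("unedited_fraction must be in [0, 1)")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")


class AlleleSim(NamedTuple):
    table: pd.DataFrame  # allele, sample_id, count (tidy)
    samples: pd.DataFrame  # sample_id, background, day, replicate
    truth: pd.DataFrame  # allele, frame_class, location


def _random_indel_allele(
    rng: np.random.Generator, p_geo: float, want_fs: bool
) -> tuple[IndelEvent, ...]:
    bases = "ACGT"
    while True:
        offset = int(rng.geometric(p_geo) - 1) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < 0.5:
            length = int(rng.geometric(0.5))
            ev = IndelEvent("deletion", offset, length)
        else:
            length = int(rng.geometric(0.5))
            seq = "".join(bases[k] for k in rng.integers(0, 4, size=length))
            ev = IndelEvent("insertion", offset, length, seq)
        is_fs = length % 3 != 0
        if is_fs == want_fs:
            return (ev,)


def simulate_amplicon_timecourse(config: AlleleSimConfig) -> AlleleSim:
    """Simulate per-allele read counts of an edited locus over time.

    Alleles are single indel events with geometric offsets around the cut
    site; the planted frameshift fraction fixes how many are FS vs NFS.
    Frequencies are Dirichlet-initialised (shared across backgrounds, as in
    an edited pool split into parallel cultures), then evolve deterministically
    as f_t ∝ f_0 * w^t before multinomial read sampling per sample.
    """
    rng = np.random.default_rng(config.seed)
    n_fs = int(round(config.n_alleles * config.frameshift_fraction))

    descriptors: list[str] = []
    classes: list[str] = []
    seen = set()
    for i in range(config.n_alleles):
        want_fs = i < n_fs
        while True:
            events = _random_indel_allele(rng, config.p_geo, want_fs)
            desc = format_descriptor(events)
            if desc not in seen:
                break
        seen.add(desc)
        descriptors.append(desc)
        classes.append(classify_allele(events))

    f0 = rng.dirichlet(np.full(config.n_alleles, config.dirichlet_alpha))
    f0 = f0 * (1.0 - config.unedited_fraction)
    if not np.any(f0 > 0):
        raise ValueError("all-zero initial allele frequencies")
    all_desc = descriptors + ["WT"]
    all_classes = classes + ["WT"]
    f0_full = np.append(f0, config.unedited_fraction)

    rows = []
    sample_rows = []
    for bg in config.backgrounds:
        w = np.array(
            [
                config.fitness.get((cls, bg), 1.0) if cls != "WT" else 1.0
                for cls in all_classes
            ]
        )
        for day in config.days:
            f = f0_full * w**day
            f = f / f.sum()
            for rep in range(1, config.replicates + 1):
                sid = f"{bg}_tp{day}_r{rep}"
                counts = rng.multinomial(config.reads_per_sample, f)
                sample_rows.append((sid, bg, day, rep))
                rows.extend(
                    (d, sid, int(c)) for d, c in zip(all_desc, counts)
                )

    from .alleles import allele_location, parse_descriptor  # local import, no cycle

    truth = pd.DataFrame(
        {
            "allele": all_desc,
            "frame_class": all_classes,
            "location": [
                allele_location(parse_descriptor(d).events) if d != "WT" else np.nan
                for d in all_desc
            ],
        }
    )
    table = pd.DataFrame(rows, columns=["allele", "sample_id", "count"])
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "background", "day", "replicate"]
    )
    return AlleleSim(table, samples, truth)


# ---------------------------------------------------------------------------
# competition assay and sensitivity panel


def simulate_competition(
    f0: float,
    s: float,
    days: Sequence[int],
    n_cells_observed: int = 10_000,
    replicates: int = 3,
    seed: int = 0,
    condition: str = "control",
) -> pd.DataFrame:
    """Simulate a FACS-read two-population competition series.

    The latent KO-cell fraction follows the logistic replicator curve
    f(t) = f0*e^(s*t) / (f0*e^(s*t) + 1 - f0); the observed fraction is a
    binomial sample of ``n_cells_observed`` cells.  Returns a tidy frame
    with columns ``day  replicate  condition  fraction_ko``.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        g = f0 * np.exp(s * day)
        f = g / (g + 1 - f0)
        for rep in range(1, replicates + 1):
            obs = rng.binomial(n_cells_observed, f) / n_cells_observed
            rows.append((day, rep, condition, obs))
    return pd.DataFrame(rows, columns=["day", "replicate", "condition", "fraction_ko"])


def competition_latent_fraction(f0: float, s: float, t: np.ndarray | float) -> np.ndarray:
    """Noise-free logistic competition curve (exposed for closed-form checks)."""
    g = f0 * np.exp(s * np.asarray(t, dtype=float))
    return g / (g + 1 - f0)


def simulate_sensitivity_panel(
    n_group_a: int,
    n_group_b: int,
    mean_a: float,
    mean_b: float,
    sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a drug-sensitivity panel over annotated cell lines.

    Group A is constructed MMR-deficient (MSI and an MMR-gene mutation),
    group B MMR-proficient (MSS, no MMR mutation); sensitivity is the log2
    viability ratio of treated vs control, drawn Normal(mean, sd) per group.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_group_a < 2 or n_group_b < 2:
        raise ValueError("need at least 2 cell lines per group")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_group_a):
        rows.append(
            (
                f"CCL_A{i + 1}",
                "MSI",
                True,
                bool(rng.random() < 0.5),
                rng.normal(mean_a, sd),
            )
        )
    for i in range(n_group_b):
        rows.append(
            (
                f"CCL_B{i + 1}",
                "MSS",
                False,
                bool(rng.random() < 0.5),
                rng.normal(mean_b, sd),
            )
        )
    return pd.DataFrame(
        rows, columns=["cell_line", "msi_status", "mmr_mutated", "tp53_lof", "sensitivity"]
    )
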