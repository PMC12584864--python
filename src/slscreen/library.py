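"""sgRNA library model and builder.

A pooled CRISPR knockout library is a flat list of guides, each carrying a
20-nt spacer and either a target gene (gene-targeting or control-gene guides)
or no target at all (non-targeting controls).  Genome-wide libraries in the
Brunello style carry ~4 guides per gene over ~19,000 genes plus non-targeting
controls; focused follow-up libraries typically use more guides per gene
(8 here) over a hit list and a positive/negative control gene panel.

The on-disk format is a TSV with columns
``sgrna_id  spacer  target_gene  category  label``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("gene_targeting", "control_gene", "non_targeting")
SPACER_ALPHABET = frozenset("ACGT")
LIBRARY_COLUMNS = ("sgrna_id", "spacer", "target_gene", "category", "label")


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: unique id, 20-nt spacer, target gene and control class."""

    sgrna_id: str
    spacer: str
    target_gene: str
    category: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for {self.sgrna_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        if len(self.spacer) != 20 or not set(self.spacer) <= SPACER_ALPHABET:
            raise ValueError(
                f"spacer for {self.sgrna_id!r} must be a 20-mer over ACGT, "
                f"got {self.spacer!r}"
            )
        if self.category == "non_targeting" and self.target_gene:
            raise ValueError(
                f"non-targeting sgRNA {self.sgrna_id!r} must have an empty target_gene"
            )
        if self.category != "non_targeting" and not self.target_gene:
            raise ValueError(
                f"{self.category} sgRNA {self.sgrna_id!r} requires a target_gene"
            )


@dataclass
class SgRNALibrary:
    """Ordered collection of :class:`SgRNARecord` with unique ids."""

    records: list[SgRNARecord] = field(default_factory=list)
    name: str = "library"

    def __post_init__(self) -> None:
        ids = [r.sgrna_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sgrna_id {dup!r} in library {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sgrna_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Distinct target genes in first-appearance order (controls included)."""
        out: dict[str, None] = {}
        for r in self.records:
            if r.target_gene:
                out.setdefault(r.target_gene)
        return list(out)

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for r in self.records:
            counts[r.category] += 1
        return counts

    def gene_map(self) -> dict[str, list[str]]:
        """gene -> list of its sgRNA ids."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.target_gene:
                out.setdefault(r.target_gene, []).append(r.sgrna_id)
        return out

    def nontargeting_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records if r.category == "non_targeting"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sgrna_id, r.spacer, r.target_gene, r.category, r.label)
                for r in self.records
            ],
            columns=list(LIBRARY_COLUMNS),
        )


def _random_spacers(n: int, rng: np.random.Generator) -> list[str]:
    # rejection sampling keeps spacers unique; collisions are vanishingly rare at 4^20
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = "".join(bases[rng.integers(0, 4, size=20)])
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def build_custom_library(
    hit_genes: list[str],
    control_genes: list[str],
    sgrnas_per_gene: int,
    n_nontargeting: int = 0,
    seed: int = 0,
    name: str = "custom",
) -> SgRNALibrary:
    """Build a focused library with ``sgrnas_per_gene`` guides per gene.

    Hit genes become ``gene_targeting`` records and control genes
    ``control_gene`` records; ``n_nontargeting`` guides against non-coding
    loci are appended.  Spacers are seeded random 20-mers (real libraries
    carry designed sequences, but nothing downstream reads sequence content).

    Raises ``ValueError`` if a gene appears in both lists or
    ``sgrnas_per_gene < 1``.
    """
    overlap = set(hit_genes) & set(control_genes)
    if overlap:
        raise ValueError(
            f"gene(s) present in both hit and control lists: {sorted(overlap)}"
        )
    if sgrnas_per_gene < 1:
        raise ValueError("sgrnas_per_gene must be >= 1")
    if n_nontargeting < 0:
        raise ValueError("n_nontargeting must be >= 0")

    rng = np.random.default_rng(seed)
    n_total = (len(hit_genes) + len(control_genes)) * sgrnas_per_gene + n_nontargeting
    spacers = iter(_random_spacers(n_total, rng))

    records: list[SgRNARecord] = []
    for category, genes in (
        ("gene_targeting", hit_genes),
        ("control_gene", control_genes),
    ):
        for gene in genes:
            for k in range(1, sgrnas_per_gene + 1):
                records.append(
                    SgRNARecord(f"{gene}_sg{k}", next(spacers), gene, category)
                )
    for k in range(1, n_nontargeting + 1):
        records.append(SgRNARecord(f"NT_sg{k}", next(spacers), "", "non_targeting"))
    return SgRNALibrary(records, name=name)


def coverage(n_cells: int, library: SgRNALibrary) -> float:
    """Fold-coverage of a library by ``n_cells`` (cells per guide)."""
    if len(library) == 0:
        raise ValueError("cannot compute coverage of an empty library")
    return n_cells / len(library)


def write_library(library: SgRNALibrary, path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_library(path, name: str | None = None) -> SgRNALibrary:
    """Read a library TSV, validating every record invariant.

    Malformed rows raise ``ValueError`` naming the 1-based data line number.
    An empty file yields an empty library with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(LIBRARY_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"library file {path} lacks required columns {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    if df.empty:
        warnings.warn(f"library file {path} contains no records", stacklevel=2)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                SgRNARecord(
                    row.sgrna_id, row.spacer, row.target_gene, row.category, row.label
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, data line {i}: {exc}") from exc
    return SgRNALibrary(records, name=name or str(path))
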