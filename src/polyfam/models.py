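"""Core record types shared across the pipeline.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive at both
ends, distances in bp between start coordinates unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Subfamilies of the AP2/EREBP superfamily plus the unclassifiable bin.
SUBFAMILIES = ("AP2", "RAV", "DREB", "ERF", "outsider")

#: Gene fates of a duplicated (homoeologous) gene pair.
FATES = (
    "conserved",
    "non_functionalization",
    "sub_functionalization",
    "dominance",
    "neo_functionalization",
)

#: Temporal response shapes of a stress time-course.
TEMPORAL_PATTERNS = ("early_peak", "biphasic", "late_peak", "constitutive", "unresponsive")

#: Stress time grid in hours; 0 h is the unstressed control.
STRESS_TIMEPOINTS = (1, 3, 6, 12, 24)


class ValidationError(ValueError):
    """An input violated a documented invariant."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: location, exon structure and chromosome rank.

    ``rank`` is the 1-based ordinal of the gene among all genes on its
    chromosome sorted by ascending start (ties broken by end, then gene_id).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} has end < start")
            if s < self.start or e > self.end:
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tied to its gene."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValidationError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass
class ExpressionMatrix:
    """A gene x condition FPKM grid with labelled, unique rows and columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.df.columns.has_duplicates:
            dups = self.df.columns[self.df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate condition labels: {dups}")
        if self.df.isna().any().any():
            r, c = next(zip(*self.df.isna().values.nonzero()))
            raise ValidationError(
                f"missing value at gene {self.df.index[r]!r}, condition {self.df.columns[c]!r}"
            )
        if (self.df.values < 0).any():
            r, c = next(zip(*(self.df.values < 0).nonzero()))
            raise ValidationError(
                f"negative FPKM at gene {self.df.index[r]!r}, condition {self.df.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.df.columns)

    def value(self, gene: str, condition: str) -> float:
        return float(self.df.at[gene, condition])


@dataclass(frozen=True)
class DomainHit:
    """A scored AP2 or B3 domain match on one protein.

    ``aligned`` carries the domain-region string indexed by profile columns
    (None for hits read from an external domain-table, which does not record
    the alignment).
    """

    protein_id: str
    domain: str
    start: int
    end: int
    score: float
    aligned: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.protein_id}: domain hit start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FamilyAssignment:
    """Per-gene subfamily, group and assigned name."""

    gene_id: str
    subfamily: str
    group: str = "none"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES + ("DREB_or_ERF", "ambiguous"):
            raise ValidationError(f"unknown subfamily {self.subfamily!r}")
        if self.group.startswith("A") and self.group != "none" and self.subfamily != "DREB":
            raise ValidationError(f"{self.gene_id}: A-group {self.group} requires DREB")
        if self.group.startswith("B") and self.subfamily != "ERF":
            raise ValidationError(f"{self.gene_id}: B-group {self.group} requires ERF")


@dataclass
class SyntenyPair:
    """Two syntenic paralogs with the Ks value of their block anchor."""

    gene_a: str
    gene_b: str
    block_id: str
    ks: float
    event: str = "unassigned"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a}")
        if not (self.ks == self.ks) or self.ks < 0:  # NaN or negative
            raise ValidationError(f"{self.gene_a}/{self.gene_b}: invalid ks {self.ks}")
        # canonical order: lexicographically smaller id first
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a


@dataclass(frozen=True)
class TandemCluster:
    """A maximal run of tandem-linked family genes on one chromosome."""

    chrom: str
    members: tuple[str, ...]
    span_bp: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("tandem cluster needs >= 2 members")


@dataclass(frozen=True)
class DatingConfig:
    """Ks windows and the synonymous-substitution clock rate.

    ``lambda_rate`` is in substitutions/synonymous site/year; the default
    maps the recent duplication peak (Ks ~ 0.65) to roughly 60 Mya.
    """

    lambda_rate: float = 5.4e-9
    recent_window: tuple[float, float] = (0.45, 1.08)
    ancient_window: tuple[float, float] = (1.50, 2.45)
    kde_bandwidth: float = 0.08

    def __post_init__(self) -> None:
        for lo, hi in (self.recent_window, self.ancient_window):
            if not lo < hi:
                raise ValidationError(f"window [{lo}, {hi}] needs lo < hi")
        if min(self.ancient_window) < self.recent_window[1] and min(self.recent_window) < self.ancient_window[1]:
            if not (self.recent_window[1] < self.ancient_window[0] or self.ancient_window[1] < self.recent_window[0]):
                raise ValidationError("Ks windows overlap")
        if self.lambda_rate <= 0:
            raise ValidationError("lambda_rate must be > 0")


@dataclass
class HomoeologPair:
    """A- and D-subgenome copies of one gene in an allotetraploid."""

    base_id: str
    a_gene: str
    d_gene: str
    bias_by_tissue: dict[str, str] = field(default_factory=dict)
    fate: str | None = None

    def __post_init__(self) -> None:
        if self.a_gene == self.d_gene:
            raise ValidationError(f"{self.base_id}: identical homoeolog ids")


@dataclass(frozen=True)
class StressCall:
    """Fold-change call for one gene at one stress timepoint.

    ``testable`` is False when the gene is expressed (FPKM > 1) in neither
    control nor treatment, in which case the call is 'unchanged' by fiat.
    """

    gene_id: str
    stress: str
    timepoint: int
    call: str
    log2fc: float
    testable: bool = True

    def __post_init__(self) -> None:
        if self.call not in ("up", "down", "unchanged"):
            raise ValidationError(f"bad call {self.call!r}")


@dataclass(frozen=True)
class TemporalPattern:
    """Shape label of one gene x stress time-course."""

    gene_id: str
    stress: str
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in TEMPORAL_PATTERNS:
            raise ValidationError(f"bad pattern {self.pattern!r}")
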