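"""Domain records shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention). GFF3 input is
converted on read. A "window" of half-width ``w`` around a point ``x`` is
closed at base resolution: a feature exactly ``w`` bases away still counts,
so as a half-open interval it is ``[x - w, x + w + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Overlap means >= 1 shared base; abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


def point_window(chrom: str, pos: int, half_width: int) -> GenomicInterval:
    """Closed +/- window around a point, as a half-open interval."""
    return GenomicInterval(chrom, max(0, pos - half_width), pos + half_width + 1)


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with a strand-aware TSS on its boundary."""

    gene_id: str
    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs a stranded interval")

    @property
    def tss(self) -> int:
        return (
            self.interval.start
            if self.interval.strand == "+"
            else self.interval.end - 1
        )


@dataclass(frozen=True)
class MirRecord:
    """A pre-miRNA locus with genomic-context and label annotations.

    ``context`` is "intragenic" when the pre-miRNA lies within a host gene on
    the same strand, else "intergenic"; the host id is present exactly for
    intragenic records.
    """

    mir_id: str
    pre_mirna: GenomicInterval
    context: str
    host_gene_id: str | None = None
    cluster_id: str | None = None
    family_id: str | None = None
    disease_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.context not in ("intergenic", "intragenic"):
            raise ValueError(f"bad context {self.context!r} for {self.mir_id}")
        if (self.context == "intragenic") != (self.host_gene_id is not None):
            raise ValueError(
                f"{self.mir_id}: intragenic MIRs (and only those) carry a host gene"
            )
        if self.pre_mirna.strand not in ("+", "-"):
            raise ValueError(f"{self.mir_id}: pre-miRNA needs a strand")

    @property
    def five_prime_end(self) -> int:
        """Strand-aware 5' end of the pre-miRNA (upstream reference point)."""
        return (
            self.pre_mirna.start
            if self.pre_mirna.strand == "+"
            else self.pre_mirna.end - 1
        )


@dataclass(frozen=True)
class Peak:
    """A binding peak (RNAPII or a chromatin mark) from one replicate.

    The peak's point location for all window tests is ``center``: the summit
    if one was provided, else the floor midpoint of the interval.
    """

    interval: GenomicInterval
    center: int
    intensity: float
    mark: str
    cell_line: str
    replicate_id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError("peak center must lie inside its interval")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


def _interval_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


@dataclass(frozen=True)
class DuplexInteraction:
    """One ChIA-PET contact joining two anchor intervals.

    Anchors are stored in canonical (lexicographic chrom, then start) order so
    duplicate records are detectable; use :func:`make_duplex` to build one from
    unordered anchors.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    cell_line: str
    replicate_id: str

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")
        if _interval_key(self.anchor_a) > _interval_key(self.anchor_b):
            raise ValueError("anchors not in canonical order; use make_duplex()")


def make_duplex(
    anchor_a: GenomicInterval,
    anchor_b: GenomicInterval,
    pet_count: int,
    cell_line: str,
    replicate_id: str,
) -> DuplexInteraction:
    if _interval_key(anchor_a) > _interval_key(anchor_b):
        anchor_a, anchor_b = anchor_b, anchor_a
    return DuplexInteraction(anchor_a, anchor_b, pet_count, cell_line, replicate_id)


@dataclass(frozen=True)
class ExpressionRecord:
    """FPKM (genes) or RPM (MIRs) for one entity in one cell line."""

    entity_id: str
    cell_line: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("expression value must be >= 0")


@dataclass(frozen=True)
class TargetPair:
    """A predicted miRNA-target relation with its database support count."""

    mir_id: str
    target_gene_id: str
    n_databases: int

    def __post_init__(self) -> None:
        if self.n_databases < 1:
            raise ValueError("n_databases must be >= 1")


@dataclass(frozen=True)
class PromoterCall:
    """TSS assignment for one MIR from the tiered evidence cascade."""

    mir_id: str
    tss: int | None
    chrom: str | None
    evidence_tier: str  # curated | cage | rnapii | none
    promoter_class: str = "unassigned"  # shared | isolated | unassigned
    shared_gene_ids: frozenset[str] = field(default_factory=frozenset)
    h3k4me3_supported: bool = False

    def __post_init__(self) -> None:
        if self.evidence_tier not in ("curated", "cage", "rnapii", "none"):
            raise ValueError(f"bad evidence tier {self.evidence_tier!r}")
        if (self.evidence_tier == "none") != (self.tss is None):
            raise ValueError("tier 'none' exactly when tss is null")
        if self.tss is None and self.promoter_class != "unassigned":
            raise ValueError("no TSS implies promoter_class 'unassigned'")
        if (self.promoter_class == "shared") != bool(self.shared_gene_ids):
            raise ValueError("'shared' exactly when shared_gene_ids is non-empty")
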