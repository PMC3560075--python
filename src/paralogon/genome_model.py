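"""Core genome data types and coordinate arithmetic.

A :class:`Genome` holds the chromosomes/scaffolds of one species together
with its family-labeled gene loci. Coordinates are 0-based, half-open base
pairs (BED convention); point positions printed in megabases by annotation
tables are stored as 1-bp loci at the printed coordinate, so their midpoint
equals the printed position. All distances are reported in Mb (1 Mb =
10^6 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import (
    CrossChromosomeError,
    ParalogonError,
    UnknownGeneError,
    UnplacedScaffoldError,
)

MB = 1_000_000

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneLocus:
    """A located gene: identifiers plus a half-open bp interval."""

    gene_id: str
    family_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    subtype_label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParalogonError(
                f"locus {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ParalogonError(
                f"locus {self.gene_id}: strand must be one of {sorted(STRANDS)}"
            )

    @property
    def midpoint_bp(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def midpoint_mb(self) -> float:
        return self.midpoint_bp / MB


@dataclass(frozen=True)
class Chromosome:
    """A chromosome, linkage group or scaffold. ``placed`` is False for
    unassembled/unplaced scaffolds, which are excluded from distance math."""

    name: str
    length: int
    placed: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParalogonError(f"chromosome {self.name}: length must be > 0")


class Genome:
    """One species' chromosomes and gene loci.

    Invariants enforced on insertion: every locus' chromosome exists, no two
    loci share a gene id, and chromosome length covers every locus.
    """

    def __init__(
        self,
        species: str,
        chromosomes: Iterable[Chromosome] = (),
        loci: Iterable[GeneLocus] = (),
    ) -> None:
        self.species = species
        self.chromosomes: dict[str, Chromosome] = {}
        self.loci: dict[str, GeneLocus] = {}
        for chrom in chromosomes:
            self.add_chromosome(chrom)
        for locus in loci:
            self.add_locus(locus)

    # -- construction ------------------------------------------------------
    def add_chromosome(self, chrom: Chromosome) -> None:
        if chrom.name in self.chromosomes:
            raise ParalogonError(
                f"{self.species}: duplicate chromosome {chrom.name}"
            )
        self.chromosomes[chrom.name] = chrom

    def add_locus(self, locus: GeneLocus) -> None:
        if locus.species != self.species:
            raise ParalogonError(
                f"locus {locus.gene_id} belongs to {locus.species}, "
                f"not {self.species}"
            )
        if locus.gene_id in self.loci:
            raise ParalogonError(
                f"{self.species}: duplicate gene id {locus.gene_id}"
            )
        chrom = self.chromosomes.get(locus.chromosome)
        if chrom is None:
            raise ParalogonError(
                f"{self.species}: locus {locus.gene_id} placed on unknown "
                f"chromosome {locus.chromosome}"
            )
        if locus.end > chrom.length:
            raise ParalogonError(
                f"{self.species}: locus {locus.gene_id} extends past the end "
                f"of {chrom.name} ({locus.end} > {chrom.length})"
            )
        self.loci[locus.gene_id] = locus

    # -- lookup ------------------------------------------------------------
    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.loci

    def __iter__(self) -> Iterator[GeneLocus]:
        return iter(self.loci.values())

    def locus(self, gene_id: str) -> GeneLocus:
        try:
            return self.loci[gene_id]
        except KeyError:
            raise UnknownGeneError(
                f"{self.species}: unknown gene {gene_id!r}"
            ) from None

    def loci_on(self, chromosome: str) -> list[GeneLocus]:
        out = [l for l in self.loci.values() if l.chromosome == chromosome]
        out.sort(key=lambda l: (l.start, l.gene_id))
        return out

    def families_on(self, chromosome: str) -> set[str]:
        return {l.family_id for l in self.loci_on(chromosome)}

    def count_family_loci(self, family_id: str) -> int:
        return sum(1 for l in self.loci.values() if l.family_id == family_id)

    # -- equality (used by round-trip tests) -------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.species == other.species
            and self.chromosomes == other.chromosomes
            and self.loci == other.loci
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Genome({self.species!r}, {len(self.chromosomes)} chromosomes, "
            f"{len(self.loci)} loci)"
        )


def _placed_midpoint(genome: Genome, gene_id: str) -> tuple[str, float]:
    locus = genome.locus(gene_id)
    chrom = genome.chromosomes[locus.chromosome]
    if not chrom.placed:
        raise UnplacedScaffoldError(
            f"{genome.species}: {gene_id} lies on unplaced scaffold "
            f"{chrom.name}; distances are defined only on placed chromosomes"
        )
    return locus.chromosome, locus.midpoint_mb


def locus_distance_mb(genome: Genome, gene_a: str, gene_b: str) -> float:
    """Distance in Mb between the midpoints of two same-chromosome genes."""
    chrom_a, mid_a = _placed_midpoint(genome, gene_a)
    chrom_b, mid_b = _placed_midpoint(genome, gene_b)
    if chrom_a != chrom_b:
        raise CrossChromosomeError(
            f"{genome.species}: {gene_a} ({chrom_a}) and {gene_b} ({chrom_b}) "
            "lie on different chromosomes; distance undefined"
        )
    return abs(mid_a - mid_b)


def region_span_mb(genome: Genome, genes: list[str]) -> float:
    """Span in Mb (max midpoint - min midpoint) of a same-chromosome gene set."""
    if not genes:
        raise ParalogonError("region_span_mb: empty gene list")
    mids = []
    chroms = set()
    for g in genes:
        chrom, mid = _placed_midpoint(genome, g)
        chroms.add(chrom)
        mids.append(mid)
    if len(chroms) > 1:
        raise CrossChromosomeError(
            f"{genome.species}: genes span chromosomes {sorted(chroms)}; "
            "span undefined"
        )
    return max(mids) - min(mids)


def count_family_loci(genome: Genome, family_id: str) -> int:
    """Number of loci of a family in the genome (0 for unknown families)."""
    return genome.count_family_loci(family_id)


def approx_mb(distance_mb: float) -> int:
    """Round a distance to integer Mb, half-up, matching the coarse
    'approximately N Mb' statements of annotation reports
    (33.33 -> 33, 7.99 -> 8, 4.62 -> 5, 10.95 -> 11)."""
    return int(math.floor(distance_mb + 0.5))
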