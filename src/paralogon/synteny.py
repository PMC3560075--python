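"""Conserved-synteny screen: chromosome blocks around focal genes and
cross-genome neighboring-gene-family selection.

The screen defines a block as a fixed radius (default 15 Mb) in each
direction of a focal gene, clamped to the chromosome — in many genomes this
covers the whole chromosome — and then selects gene families represented on
several blocks across two anchor genomes. Two anchoring rules are
supported: *dual_anchor* (two blocks per genome: families on both blocks of
the primary genome, plus families on both secondary-genome blocks that hit
at least one primary block) and *triple_anchor* (three blocks per genome:
families on all three blocks of either genome).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ParalogonError, UnplacedScaffoldError
from .genome_model import MB, Genome


@dataclass(frozen=True)
class ChromosomeBlock:
    """A half-open bp interval on one chromosome, centered on a focal gene."""

    species: str
    chromosome: str
    start: int
    end: int
    focal_gene: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParalogonError(
                f"block on {self.chromosome}: require 0 <= start < end"
            )

    @property
    def start_mb(self) -> float:
        return self.start / MB

    @property
    def end_mb(self) -> float:
        return self.end / MB


def define_block(
    genome: Genome, focal_gene: str, radius_mb: float = 15.0
) -> ChromosomeBlock:
    """The interval ±radius around the focal gene's midpoint, clamped to
    the chromosome (whole chromosome when the radius exceeds it)."""
    locus = genome.locus(focal_gene)
    chrom = genome.chromosomes[locus.chromosome]
    if not chrom.placed:
        raise UnplacedScaffoldError(
            f"{genome.species}: focal gene {focal_gene} lies on unplaced "
            f"scaffold {chrom.name}; block undefined"
        )
    mid = locus.midpoint_bp
    radius = radius_mb * MB
    start = max(0, int(round(mid - radius)))
    end = min(chrom.length, int(round(mid + radius)))
    return ChromosomeBlock(genome.species, chrom.name, start, end, focal_gene)


def families_in_block(
    block: ChromosomeBlock, genome: Genome, min_members: int = 1
) -> set[str]:
    """Families with >= ``min_members`` loci whose midpoints fall in the
    half-open block interval (a midpoint exactly at the end is excluded)."""
    if block.species != genome.species:
        raise ParalogonError(
            f"block belongs to {block.species}, not {genome.species}"
        )
    counts: dict[str, int] = {}
    for locus in genome.loci_on(block.chromosome):
        if block.start <= locus.midpoint_bp < block.end:
            counts[locus.family_id] = counts.get(locus.family_id, 0) + 1
    return {fam for fam, n in counts.items() if n >= min_members}


@dataclass
class AnchorSpec:
    """Which genomes and blocks anchor the family screen."""

    mode: str  # "dual_anchor" | "triple_anchor"
    primary_species: str
    primary_blocks: list[ChromosomeBlock]
    secondary_species: str
    secondary_blocks: list[ChromosomeBlock]

    def __post_init__(self) -> None:
        need = {"dual_anchor": 2, "triple_anchor": 3}.get(self.mode)
        if need is None:
            raise ConfigurationError(f"unknown anchor mode {self.mode!r}")
        for name, blocks in (
            (self.primary_species, self.primary_blocks),
            (self.secondary_species, self.secondary_blocks),
        ):
            if len(blocks) != need:
                raise ConfigurationError(
                    f"{self.mode} requires exactly {need} blocks per genome; "
                    f"{name} has {len(blocks)}"
                )


def select_neighbor_families(
    spec: AnchorSpec,
    genomes: dict[str, Genome],
    min_members: int = 1,
    include_focal: bool = True,
    focal_family: str | None = None,
) -> list[str]:
    """Gene families selected by the conserved-synteny anchor rule,
    lexicographically sorted.

    dual_anchor: families on BOTH primary blocks, union families on BOTH
    secondary blocks that also hit >= 1 primary block. triple_anchor:
    families on all three blocks of the primary genome, union families on
    all three blocks of the secondary genome.
    """
    for sp in (spec.primary_species, spec.secondary_species):
        if sp not in genomes:
            raise ParalogonError(f"anchor genome {sp!r} not provided")
    prim = [
        families_in_block(b, genomes[spec.primary_species], min_members)
        for b in spec.primary_blocks
    ]
    seco = [
        families_in_block(b, genomes[spec.secondary_species], min_members)
        for b in spec.secondary_blocks
    ]
    if spec.mode == "dual_anchor":
        selected = set.intersection(*prim) | (
            set.intersection(*seco) & set.union(*prim)
        )
    else:
        selected = set.intersection(*prim) | set.intersection(*seco)
    if not include_focal and focal_family is not None:
        selected.discard(focal_family)
    return sorted(selected)


class FamilyLocationTable:
    """Long-form chart of family member locations: one row per located
    gene, deterministically ordered by (family, species, chromosome,
    position)."""

    COLUMNS = ["family_id", "species", "chromosome", "gene_id", "pos_mb"]

    def __init__(self, frame: pd.DataFrame, families: list[str] | None = None):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ParalogonError(f"table lacks columns {sorted(missing)}")
        self.frame = (
            frame[self.COLUMNS]
            .sort_values(self.COLUMNS[:4], kind="mergesort")
            .reset_index(drop=True)
        )
        # families charted even when no member gene was located
        observed = set(self.frame["family_id"].unique())
        self.all_families = sorted(observed | set(families or ()))

    @property
    def families(self) -> list[str]:
        return list(self.all_families)

    @property
    def n_families(self) -> int:
        return len(self.all_families)

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def for_species(self, species: str) -> "FamilyLocationTable":
        return FamilyLocationTable(
            self.frame[self.frame["species"] == species].copy()
        )

    def cell(self, family_id: str, species: str, chromosome: str) -> list[str]:
        f = self.frame
        sel = f[
            (f["family_id"] == family_id)
            & (f["species"] == species)
            & (f["chromosome"] == chromosome)
        ]
        return list(sel["gene_id"])

    def to_wide(self) -> pd.DataFrame:
        """Wide chart: rows = families, column groups = (species,
        chromosome), cells = 'gene@pos' entries joined by ';'."""
        f = self.frame.copy()
        f["entry"] = f["gene_id"] + "@" + f["pos_mb"].map("{:.2f}".format)
        wide = f.pivot_table(
            index="family_id",
            columns=["species", "chromosome"],
            values="entry",
            aggfunc=lambda s: ";".join(s),
            fill_value="",
        )
        return wide.reindex(self.all_families, fill_value="").sort_index()

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", index=False, float_format="%.4f")

    def to_json(self) -> str:
        records: dict = {}
        for (fam, sp, chrom), group in self.frame.groupby(
            ["family_id", "species", "chromosome"], sort=True
        ):
            records.setdefault(fam, {}).setdefault(sp, {})[chrom] = [
                {"gene_id": g, "pos_mb": round(p, 4)}
                for g, p in zip(group["gene_id"], group["pos_mb"])
            ]
        import json

        return json.dumps(records, sort_keys=True, indent=1)

    @classmethod
    def from_tsv(cls, text: str) -> "FamilyLocationTable":
        from io import StringIO

        return cls(pd.read_csv(StringIO(text), sep="\t"))


def tabulate_family_locations(
    families: list[str], genomes: dict[str, Genome]
) -> FamilyLocationTable:
    """Chart the locations of the given families across genomes."""
    rows = []
    wanted = set(families)
    for species in sorted(genomes):
        for locus in genomes[species]:
            if locus.family_id in wanted:
                rows.append(
                    {
                        "family_id": locus.family_id,
                        "species": species,
                        "chromosome": locus.chromosome,
                        "gene_id": locus.gene_id,
                        "pos_mb": locus.midpoint_mb,
                    }
                )
    frame = pd.DataFrame(rows, columns=FamilyLocationTable.COLUMNS)
    return FamilyLocationTable(frame, families=families)
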