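"""Readers/writers for gene coordinate tables and gene-family trees.

Gene table TSV columns: ``species chromosome start end strand gene_id
family_id subtype_label`` (header required, ``#`` comments allowed).
Chromosome lengths travel in a sidecar TSV with columns ``species
chromosome length placed``; chromosomes absent from the sidecar default to
placed with a generous length margin beyond the last locus. The pair of
files round-trips a set of :class:`~paralogon.genome_model.Genome` objects
losslessly.
"""

from __future__ import annotations

import pathlib

import dendropy

from .errors import ParseError, SchemaError
from .genome_model import Chromosome, GeneLocus, Genome
from .tree_timing import DEFAULT_LEAF_RE, GeneFamilyTree

GENE_COLUMNS = [
    "species",
    "chromosome",
    "start",
    "end",
    "strand",
    "gene_id",
    "family_id",
    "subtype_label",
]
LENGTH_COLUMNS = ["species", "chromosome", "length", "placed"]

#: length assigned to chromosomes missing from the sidecar: last locus end
#: plus this margin (bp)
DEFAULT_LENGTH_MARGIN = 60_000_000


def _parse_rows(text: str, columns: list[str], what: str):
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = set(columns) - set(header)
            if missing:
                raise SchemaError(
                    f"{what}: missing required column(s) "
                    f"{sorted(missing)} in header"
                )
            continue
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        yield lineno, dict(zip(header, fields))
    if header is None:
        raise SchemaError(f"{what}: empty file (header row required)")


def _int_field(row: dict, key: str, lineno: int, what: str) -> int:
    try:
        return int(row[key])
    except ValueError:
        raise ParseError(
            f"{what} line {lineno}: non-integer {key} {row[key]!r}"
        ) from None


def genomes_from_tables(
    gene_tsv: str, lengths_tsv: str | None = None
) -> dict[str, Genome]:
    """Parse a gene table (and optional lengths sidecar) into genomes."""
    lengths: dict[tuple[str, str], tuple[int, bool]] = {}
    if lengths_tsv is not None:
        for lineno, row in _parse_rows(
            lengths_tsv, LENGTH_COLUMNS, "lengths table"
        ):
            length = _int_field(row, "length", lineno, "lengths table")
            placed = row["placed"].strip().lower() in {"1", "true", "yes"}
            lengths[(row["species"], row["chromosome"])] = (length, placed)

    rows = []
    seen: dict[tuple[str, str], int] = {}
    for lineno, row in _parse_rows(gene_tsv, GENE_COLUMNS, "gene table"):
        key = (row["species"], row["gene_id"])
        if key in seen:
            raise ParseError(
                f"gene table line {lineno}: duplicate gene id "
                f"{row['gene_id']!r} for {row['species']} "
                f"(first seen on line {seen[key]})"
            )
        seen[key] = lineno
        rows.append(
            (
                lineno,
                row["species"],
                row["chromosome"],
                _int_field(row, "start", lineno, "gene table"),
                _int_field(row, "end", lineno, "gene table"),
                row["strand"] or ".",
                row["gene_id"],
                row["family_id"],
                row["subtype_label"] or None,
            )
        )

    genomes: dict[str, Genome] = {}
    max_end: dict[tuple[str, str], int] = {}
    for _, species, chrom, start, end, *_ in rows:
        key = (species, chrom)
        max_end[key] = max(max_end.get(key, 0), end)
    for (species, chrom), (length, placed) in lengths.items():
        genome = genomes.setdefault(species, Genome(species))
        if chrom not in genome.chromosomes:
            genome.add_chromosome(Chromosome(chrom, length, placed))
    for (species, chrom), end in sorted(max_end.items()):
        genome = genomes.setdefault(species, Genome(species))
        if chrom not in genome.chromosomes:
            genome.add_chromosome(
                Chromosome(chrom, end + DEFAULT_LENGTH_MARGIN, True)
            )
    for lineno, species, chrom, start, end, strand, gene, fam, sub in rows:
        try:
            genomes[species].add_locus(
                GeneLocus(
                    gene_id=gene,
                    family_id=fam,
                    species=species,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subtype_label=sub,
                )
            )
        except Exception as exc:
            raise ParseError(f"gene table line {lineno}: {exc}") from exc
    return genomes


def genomes_to_tables(genomes: dict[str, Genome]) -> tuple[str, str]:
    """Serialize genomes to (gene table TSV, lengths sidecar TSV)."""
    gene_lines = ["\t".join(GENE_COLUMNS)]
    length_lines = ["\t".join(LENGTH_COLUMNS)]
    for species in sorted(genomes):
        genome = genomes[species]
        for name in sorted(genome.chromosomes):
            chrom = genome.chromosomes[name]
            length_lines.append(
                f"{species}\t{name}\t{chrom.length}\t"
                f"{'true' if chrom.placed else 'false'}"
            )
            for locus in genome.loci_on(name):
                gene_lines.append(
                    "\t".join(
                        [
                            species,
                            name,
                            str(locus.start),
                            str(locus.end),
                            locus.strand,
                            locus.gene_id,
                            locus.family_id,
                            locus.subtype_label or "",
                        ]
                    )
                )
    return "\n".join(gene_lines) + "\n", "\n".join(length_lines) + "\n"


def genome_to_tsv(genome: Genome) -> str:
    """Gene table TSV for one genome (no sidecar)."""
    return genomes_to_tables({genome.species: genome})[0]


def read_gene_table(
    path, lengths_path=None
) -> dict[str, Genome]:
    gene_tsv = pathlib.Path(path).read_text()
    lengths_tsv = (
        pathlib.Path(lengths_path).read_text()
        if lengths_path is not None
        else None
    )
    return genomes_from_tables(gene_tsv, lengths_tsv)


def write_gene_table(genomes: dict[str, Genome], path, lengths_path=None):
    gene_tsv, lengths_tsv = genomes_to_tables(genomes)
    pathlib.Path(path).write_text(gene_tsv)
    if lengths_path is not None:
        pathlib.Path(lengths_path).write_text(lengths_tsv)


# ---------------------------------------------------------------------------
# newick


def read_newick(
    source,
    leaf_regex=DEFAULT_LEAF_RE,
    outgroup: str | None = None,
    method: str | None = None,
    family_id: str | None = None,
) -> GeneFamilyTree:
    """Read a gene-family tree from a newick file or string.

    Internal node labels are interpreted as support values when numeric.
    When ``outgroup`` names a leaf, the (possibly unrooted) tree is rooted
    on the edge above that leaf.
    """
    text = source
    p = pathlib.Path(str(source))
    if "(" not in str(source) and p.exists():
        text = p.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"invalid newick: {exc}") from exc
    if outgroup is not None:
        target = None
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label == outgroup:
                target = leaf
                break
        if target is None:
            raise ParseError(
                f"outgroup leaf {outgroup!r} not present; cannot root"
            )
        tree.reroot_at_edge(target.edge, update_bipartitions=False)
    return GeneFamilyTree(
        tree, leaf_regex=leaf_regex, method=method, family_id=family_id
    )


def write_newick(gft: GeneFamilyTree) -> str:
    return gft.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
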