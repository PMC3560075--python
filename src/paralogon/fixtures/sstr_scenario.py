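"""The proposed SSTR evolutionary scheme as an explicit event history.

Two ancestral vertebrate SSTR genes on two different chromosomes duplicate
in 2R: one gives rise to SSTR1, -4 and -6 (the fourth 2R product is lost),
the other to SSTR2, -3 and -5. SSTR6 is then lost in the tetrapod lineage
and SSTR4 in the ray-finned lineage before the gar–teleost split. On the
teleost (zebrafish) lineage, three of the four 2R-generated SSTR2/-3/-5
blocks fuse before 3R, 3R doubles the repertoire, one 3R copy each of
SSTR1 and SSTR6 is lost, and a post-3R fission splits one of the fused,
duplicated blocks — yielding the eight-gene zebrafish repertoire (SSTR1,
-2a, -2b, -3a, -3b, -5a, -5b, -6) and the six-gene post-2R vertebrate
ancestor.

Replaying this history with :func:`paralogon.evo_sim.replay_events`
reproduces those gene counts mechanically; the chromosome and gene
identifiers below follow the replay engine's naming convention.
"""

from __future__ import annotations

from ..evo_sim import EventHistory, EvoEvent
from ..genome_model import Chromosome, GeneLocus, Genome
from ..species_tree import SpeciesTree, WgdMarker

SCENARIO_NEWICK = (
    "(amphioxus:1.0,((human:1.0,coelacanth:1.0)sarcopterygian_crown:1.0,"
    "(gar:1.0,zebrafish:1.0)gar_teleost_split:1.0)vertebrate_crown:1.0)"
    "chordate_vertebrate_split;"
)

# replay-engine names of the 2R products of the two ancestral genes
_S145 = "SSTR145"  # ancestor of SSTR1/-4/-6
_S235 = "SSTR235"  # ancestor of SSTR2/-3/-5
SSTR1 = f"{_S145}_2Ra0_2Rb0"
SSTR4 = f"{_S145}_2Ra0_2Rb1"
SSTR6 = f"{_S145}_2Ra1_2Rb0"
SSTR2 = f"{_S235}_2Ra0_2Rb0"
SSTR3 = f"{_S235}_2Ra0_2Rb1"
SSTR5 = f"{_S235}_2Ra1_2Rb0"

_CHR_2 = "chrB_2Ra0_2Rb0"  # SSTR2-bearing 2R block
_CHR_3 = "chrB_2Ra0_2Rb1"  # SSTR3-bearing 2R block
_CHR_5 = "chrB_2Ra1_2Rb0"  # SSTR5-bearing 2R block
_FUSED_23 = f"{_CHR_2}+{_CHR_3}"
_FUSED_235 = f"{_FUSED_23}+{_CHR_5}"


def scenario_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(
        SCENARIO_NEWICK,
        wgd_markers=[
            WgdMarker("2R-a", above="vertebrate_crown", position=0.3),
            WgdMarker("2R-b", above="vertebrate_crown", position=0.6),
            WgdMarker("3R", above="zebrafish", position=0.5),
        ],
    )


def scenario_ancestor() -> Genome:
    """Two ancestral SSTR genes on two different chromosomes."""
    genome = Genome("ancestor")
    for chrom, gene in (("chrA", _S145), ("chrB", _S235)):
        genome.add_chromosome(Chromosome(chrom, 2_000_000, placed=True))
        genome.add_locus(
            GeneLocus(
                gene_id=gene,
                family_id="SSTR",
                species="ancestor",
                chromosome=chrom,
                start=500_000,
                end=501_000,
                strand="+",
            )
        )
    return genome


def scenario_history() -> EventHistory:
    events = [
        # 2R on the vertebrate stem; one product of each ancestral gene lost
        EvoEvent("wgd", "vertebrate_crown", {"label": "2R-a"}),
        EvoEvent("wgd", "vertebrate_crown", {"label": "2R-b"}),
        EvoEvent(
            "gene_loss", "vertebrate_crown", {"gene": f"{_S145}_2Ra1_2Rb1"}
        ),
        EvoEvent(
            "gene_loss", "vertebrate_crown", {"gene": f"{_S235}_2Ra1_2Rb1"}
        ),
        # SSTR6 lost in the tetrapod lineage
        EvoEvent("gene_loss", "human", {"gene": SSTR6}),
        # coelacanth keeps all six, plus a lineage-specific SSTR2 duplicate
        EvoEvent("lineage_duplication", "coelacanth", {"gene": SSTR2}),
        # SSTR4 lost in the ray-finned lineage before the gar-teleost split
        EvoEvent("gene_loss", "gar_teleost_split", {"gene": SSTR4}),
        # teleost lineage: three 2R blocks fuse before 3R
        EvoEvent(
            "chromosome_fusion",
            "zebrafish",
            {
                "left": _CHR_2,
                "right": _CHR_3,
                "flip_right": False,
                "name": _FUSED_23,
            },
        ),
        EvoEvent(
            "chromosome_fusion",
            "zebrafish",
            {
                "left": _FUSED_23,
                "right": _CHR_5,
                "flip_right": False,
                "name": _FUSED_235,
            },
        ),
        EvoEvent("wgd", "zebrafish", {"label": "3R"}),
        # only one 3R copy each of SSTR1 and SSTR6 is conserved
        EvoEvent("gene_loss", "zebrafish", {"gene": f"{SSTR1}_3R1"}),
        EvoEvent("gene_loss", "zebrafish", {"gene": f"{SSTR6}_3R1"}),
        # one of the fused, duplicated blocks splits by fission after 3R
        EvoEvent(
            "chromosome_fission",
            "zebrafish",
            {"chromosome": f"{_FUSED_235}_3R1", "index": 1},
        ),
    ]
    return EventHistory(events)
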