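# paralogon

Detection of paralogons — chromosome regions related by whole-genome
duplication — with relative dating of the duplications and inference of
the chromosome rearrangements that obscure them.

Vertebrate gene families that expanded in the two basal whole-genome
duplications (2R) and the teleost-specific third round (3R) leave two
linked signals: duplication nodes in their gene trees whose descendant
taxa date them into windows between named speciations, and conserved
synteny between the chromosome regions that carry the duplicates. This
package is for comparative genomicists who want to run that combined
analysis from plain files: per-species gene coordinate tables (TSV),
rooted gene-family trees (newick, leaves `SPECIES|GENE`), and a species
tree with named divergences and WGD placements (YAML).

The core operations:

- **blocks & screen** — ±15 Mb chromosome blocks around focal genes and
  set-algebra selection of neighboring gene families represented across
  blocks of two anchor genomes (dual- and triple-anchor rules);
- **reconciliation & dating** — LCA mapping of gene trees onto the
  species tree (a node is a duplication iff its mapping *M* equals the
  mapping of one of its children), and window assignment: a duplication
  dates to window *(A, B]* iff *M* lies strictly below node *A* and at or
  above node *B* (e.g. 2R = between the invertebrate-chordate/vertebrate
  split and the sarcopterygian/actinopterygian split);
- **paralogon assembly** — connected components of the region graph whose
  edges carry ≥ 2 families with window-dated paralogs on both sides;
- **rearrangement timing** — the key inference: if the duplicates
  co-located on a teleost chromosome are 2R-generated paralogs of many
  families (not 3R a/b duplicates of one class), the underlying fusion
  happened *before* 3R;
- **a simulator** (`evo_sim`) that evolves genomes and true gene trees
  under WGD, loss, fusion, fission, translocation and shuffling, logging
  every event, so that the whole inference chain can be validated against
  known truth (`simulate → infer → reconstruct → replay`).

Packaged fixtures encode the published somatostatin-receptor (SSTR)
locus chart across 15 vertebrate genomes, the two neighboring-family
screens (17 + 30 = 47 families), and the SSTR evolutionary scheme as an
explicit, replayable event history.

## Worked example

```python
from paralogon import fixtures as fx
from paralogon.genome_model import locus_distance_mb, approx_mb
from paralogon.synteny import define_block
from paralogon.evo_sim import replay_events, state_at

genomes = fx.sstr_genomes()
d = locus_distance_mb(genomes["zebrafish"], "SSTR2a", "SSTR3a")
print(f"zebrafish SSTR2a-SSTR3a: {d:.2f} Mb (~{approx_mb(d)} Mb)")

block = define_block(genomes["human"], "SSTR1", radius_mb=15)
print(f"human SSTR1 screen window: chr{block.chromosome} "
      f"{block.start_mb:.2f}-{block.end_mb:.2f} Mb")

tips = replay_events(fx.scenario_history(), fx.scenario_ancestor(),
                     fx.scenario_species_tree())
print("zebrafish SSTR repertoire after replay:",
      tips["zebrafish"].count_family_loci("SSTR"))
```

prints

```
zebrafish SSTR2a-SSTR3a: 33.33 Mb (~33 Mb)
human SSTR1 screen window: chr14 23.68-53.68 Mb
zebrafish SSTR repertoire after replay: 8
```

The 33.33 Mb distance is the separation of the two co-located 2R paralogs
on zebrafish chromosome 3 — co-location of 2R (not 3R) duplicates is the
signature of a chromosome fusion that predates 3R. The 23.68–53.68 Mb
interval is the conserved-synteny screen window around human SSTR1. The
replayed scheme — 2R, reciprocal losses, three blocks fused before 3R, 3R,
two more losses, one fission — yields the eight-gene zebrafish repertoire
(SSTR1, -2a, -2b, -3a, -3b, -5a, -5b, -6); truncated at the post-2R
vertebrate ancestor (`state_at(..., "vertebrate_crown")`) it yields six.

A CLI mirrors the library (`paralogon simulate|blocks|classify|paralogons|
scenario|run`); `paralogon run --seed 2 --out out/` writes gene tables,
verdicts, paralogons, the reconstructed scenario and a summary JSON.

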