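# Methods

## Problem and approach

Vertebrate genomes carry the footprint of two rounds of whole-genome
duplication at the base of vertebrate evolution (2R) and a third,
teleost-specific round (3R). A gene family that expanded through these
events leaves two kinds of evidence: (i) its gene tree contains duplication
nodes whose descendant taxa bracket the duplication into a time window
between named speciations, and (ii) the chromosome regions carrying the
duplicates share many *other* families with the same duplication history —
a paralogon. Chromosome fusions, fissions and translocations, frequent in
teleost lineages, scramble this signal; the package's purpose is to detect
paralogons despite such rearrangements and to time the rearrangements
themselves relative to 3R.

The pipeline consumes per-species gene coordinate tables, rooted
gene-family trees (newick, leaves `SPECIES|GENE`), and a species tree with
named divergence nodes and WGD placements. Its stages:

1. **Conserved-synteny screen** (`synteny`). A chromosome block is the
   ±15 Mb interval around a focal gene, clamped to the chromosome (often
   the whole chromosome). Neighboring families are selected by set algebra
   over block membership under two anchoring rules: *dual anchor* (two
   blocks per genome: families on both blocks of the primary genome, plus
   families on both secondary-genome blocks hitting at least one primary
   block) and *triple anchor* (families on all three blocks of either
   genome). Membership uses the locus midpoint against the half-open block
   interval; "represented" means ≥ 1 member by default (configurable),
   since the sources the screen emulates do not state a stricter count.
2. **Reconciliation and relative dating** (`tree_timing`). Gene trees are
   LCA-mapped onto the species tree (Zmasek–Eddy): a node is a duplication
   iff it maps to the same species-tree node as one of its children.
   Duplications are dated into windows bounded by two named species-tree
   nodes — strictly after the older bound, at or before the younger. The
   packaged windows are 2R = (chordate/vertebrate split,
   sarcopterygian/actinopterygian split] and 3R = (gar–teleost split,
   teleost crown]. A duplication mapping to a single extant taxon is
   lineage-specific. No molecular clock is used anywhere.
3. **Family verdicts**. A family *supports* a WGD if at least one
   phylogenetic method (e.g. ML and NJ trees of the same leaf set) shows a
   window-dated duplication with node support ≥ threshold (default 50 on
   the percent scale; values ≤ 1 are read as proportions ×100); it is
   *consistent* if such a duplication exists only below threshold or under
   a single method; otherwise *inconclusive*. This tri-state rule is an
   explicit codification of practice that is usually narrative; the rule
   text is attached to every verdict (`FamilyVerdict.rule`). Trees without
   recorded supports (the simulator's truth trees) count as supported.
4. **Paralogon assembly** (`paralogons`). Regions are (species,
   chromosome) pairs. Within a genome, two regions are linked when ≥
   `min_support` (default 2) families hold window-dated paralogs of one
   another on them; across genomes, when they share orthologs of the same
   window class. Paralogons are the connected components. `min_support=2`
   because a single shared family (typically the focal family itself)
   cannot distinguish synteny from coincidence.
5. **Rearrangement timing**. A chromosome co-locating ≥ `min_support`
   families' *distinct 2R classes* witnesses a fusion dated before 3R;
   when only 3R a/b duplicates of one 2R class are co-located the event
   postdates 3R; ties and genomes without 3R in their ancestry give
   `indeterminate`. Conflicting family evidence is resolved by majority.
   A paralogy class is the tuple of child indices taken at window-dated
   duplication nodes on the root-to-leaf path of the family's tree, so
   classes are comparable across species (same tree) but not across
   families — merging of calls across chromosomes therefore uses matching
   per-family class pairs, not raw class labels.
6. **Small-block detection**. Orthology groups (family + class in every
   dating window) that sit on one reference chromosome but are split
   across derived chromosomes mark moved genes; moved genes clustered
   within a configurable window (default 0.5 Mb) on the derived chromosome
   are reported as one block-translocation call with its interval. The
   in-place derived chromosome for a reference cohort is the one that the
   cohort itself dominates, which keeps a large moved block from being
   mistaken for the resident copy.
7. **Scenario reconstruction**. Calls are ordered into a replayable event
   history: WGDs from the species-tree markers in branch-major pre-order,
   before-3R fusions ahead of the 3R event on its branch, post-3R events
   behind it. In *truth mode* (ancestral genome and tip genomes supplied,
   as in simulator validation) exact payloads — fusion partners and
   orientation, fission breakpoints — are recovered by mapping observed
   gene identifiers back through the replay engine's deterministic naming
   scheme; the reconstructed history then replays to the observed tips.
   With real annotation identifiers this recovery is not available and the
   scenario degrades to region-level calls flagged as unordered groups.
   Calls with contradictory timing raise a conflict report rather than
   being silently resolved.

## The simulator

`evo_sim` evolves an ancestral genome along the species tree under WGD
(chromosome-set duplication with immediate per-copy Bernoulli retention),
gene loss, end-to-end fusion with optional orientation flip, fission at an
intergenic breakpoint, translocation of a contiguous gene run (geometric
block length), intrachromosomal shuffling and tandem duplication. Every
applied event — including the retention losses following each WGD — is
logged, and simulation and replay share one event-application engine, so
`replay_events(truth, ancestor)` reproduces the tip genomes exactly.
True gene trees are grown alongside, with WGD duplication nodes tagged by
their labels and branch lengths proportional to species-tree depth.

Deliberate simplifications, and what they imply for the tests: losses are
immediate rather than spread over time (delayed loss would only relabel
some duplications as lineage-specific); coordinates are re-spaced
uniformly at 1 Mb per gene after every event, because the inference stages
use only order and co-location, never exact base pairs; there is no
sequence evolution, so tree-inference error is modeled separately by
random NNI perturbation (`perturb_gene_tree`). Passing tests therefore
show that the inference logic is correct given trees of stated quality;
they do not probe alignment or tree-inference artifacts of real data.

Default study conditions (used by the validation suites): 30 gene
families, ohnolog retention probability 0.9 per copy per WGD,
rearrangement rates 0 unless events are planted explicitly, one global
generator seeded once, events sampled branch-major in pre-order. The
recovery experiments plant one fusion on the pre-3R segment of the
teleost stem and measure detection over 20 seeds; with unperturbed trees
detection is exact, and the same experiment is repeated with 2 NNI moves
per tree as a robustness report.

## Numerical and formatting choices

- Coordinates are 0-based half-open bp; point positions printed in Mb by
  annotation tables are stored as 1-bp loci at the printed coordinate
  (×10⁶ exactly, no re-rounding), so midpoints equal printed positions.
- Distances are reported in Mb to two decimals; comparisons against
  coarse "approximately N Mb" statements use round-half-up to integer
  (`approx_mb`: 33.33→33, 7.99→8, 4.62→5, 10.95→11).
- Unplaced scaffolds carry `placed=false` and refuse distance/span/block
  operations. Chromosomes missing from the lengths sidecar default to the
  last locus end plus 60 Mb, placed.
- Block membership ties at the interval end are excluded (half-open).
- Soft polytomies in gene trees are accepted with a warning; LCA labels
  are computed directly on the polytomy.
- Support scale is auto-detected per tree: any value > 1 ⇒ percent.

## Packaged fixtures

The fixture genomes encode the published somatostatin-receptor (SSTR)
locus chart across 15 species; the two neighboring-family screens (17
families for the SSTR1/-4/-6 blocks, 30 for SSTR2/-3/-5, 47 combined) are
shipped as TSV. One chart entry (anole SSTR1) has no printed location and
is omitted. Two published statements disagree with the chart's own
coordinates: green puffer SSTR2a/-3a are placed on chromosome 8 in prose
but chromosome 3 in the chart (the fixture follows the chart), and the
stickleback SSTR2a/3a/5a span is "9 Mb" in prose but 6.09 Mb from the
chart coordinates (the code computes 6.09; both readings are noted here
rather than reconciled). Chromosome lengths are included where published
(chicken 14/18, stickleback V/IX/XI); scaffold lengths are synthetic
placeholders marked as such in the sidecar.

`fixtures.sstr_scenario` encodes the SSTR evolutionary scheme as an
explicit event history: 2R on the vertebrate stem with one loss per
ancestral gene (six subtypes in the post-2R ancestor), SSTR6 lost in
tetrapods and SSTR4 in ray-finned fishes, three 2R blocks fused before 3R
on the teleost lineage, 3R, loss of one copy each of SSTR1 and SSTR6, and
a post-3R fission — replaying to the eight-gene zebrafish repertoire.

## Pipeline configuration (YAML)

```yaml
mode: simulate            # or "tables" (chart packaged/supplied genomes)
seed: 0
out_dir: out
radius_mb: 15.0
anchor_mode: dual_anchor  # or triple_anchor
support_threshold: 50.0
min_support: 2
species_tree:             # optional; defaults to the packaged tree
  newick: "(...)chordate_vertebrate_split;"
  wgd: [{label: 2R-a, above: ..., position: 0.33}, ...]
  windows: [{label: 2R_window, older_bound: ..., younger_bound: ...}, ...]
sim:                      # simulate mode
  n_families: 30
  n_ancestral_chromosomes: 1
  ohnolog_retention_prob: 0.9
  planted_events:
    - {kind: chromosome_fusion, branch: teleost_crown, before_wgd: 3R}
```

## Known limitations

- Fusion-vs-translocation timing is decided from co-location signatures
  alone; a post-3R translocation between chromosomes of *different* 2R
  classes is indistinguishable from a pre-3R fusion without additional
  evidence (the duplicated-signature on both 3R copies usually breaks the
  tie, and is what the merging step exploits, but it is not asserted).
- Exact scenario payload recovery requires the simulator's lineage-stable
  identifiers; real data yields region-level narratives only.
- Finer orderings among post-3R events (which translocation preceded
  which fission) are reported as unordered groups, not resolved.
- Gene-order statistics (intrachromosomal shuffling intensity) are
  simulated but not used as evidence.
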