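# Neighboring gene families screened for conserved synteny in the
# SSTR1/-4/-6-bearing chromosome blocks (dual-anchor screen: human + chicken).
# root column: outgroup used to root the family tree when not fruit fly.
symbol	description	root
ABHD12	Abhydrolase domain containing 12
CFL	Cofilin and destrin (actin depolymerizing factor)
FLRT	Fibronectin leucine rich transmembrane protein	C. savignyi
FOXA	Forkhead box A
ISM	Isthmin homolog	C. intestinalis
JAG	Jagged
NIN	Ninein (GSK3B interacting protein)
NKX2	NK2 homeobox 1 and 4
PAX	Paired box 1 and 9
PYG	Glycogen phosphorylase; brain, liver and muscle variants
RALGAPA	Ral GTPase activating protein, alpha subunit
RIN	Ras and Rab interactor
SEC23	Sec23 homologs A and B
SLC24A	Solute carrier family 24 members 3 and 4	B. floridae
SNX	Sorting nexin 5, 6 and 32
SPTLC	Serine palmitoyltransferase, long chain base subunit 2 and 3
VSX	Visual system homeobox	C. elegans
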