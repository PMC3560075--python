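# Neighboring gene families screened for conserved synteny in the
# SSTR2/-3/-5-bearing chromosome blocks (triple-anchor screen: chicken +
# stickleback). root column: outgroup used when not fruit fly.
symbol	description	root
ADAP	ArfGAP with dual PH domains
ATP2A	ATPase, Ca++ transporting, cardiac muscle, fast twitch
C1QTNF	C1q and tumor necrosis factor related protein	B. floridae
CABP	Calcium binding protein 1, 3, 4 and 5
CACNA1	Calcium channel, voltage dependent, T type alpha subunit
CREBBP	CREB binding protein
CYTH	Cytohesin
FAM20	Family with sequence similarity 20
FNG	Fringe homolog
FSCN	Fascin homolog 1 and 2, actin-bundling protein
GGA	Golgi-associated, gamma adapting ear containing, ARF-binding protein
GLPR	Glucagon, glucagon-like and gastric inhibitory polypeptide receptors	C. intestinalis
GRIN2	Glutamate receptor, ionotropic, N-methyl D-aspartate 2
KCNJ	Potassium inwardly-rectifying channel, subfamily J member 2, 4, 12 and 14	C. intestinalis
KCTD	Potassium channel tetramerisation domain containing 2, 5 and 17
METRN	Meteorin, glial cell differentiation regulator	B. floridae
NDE	nudE nuclear distribution gene E homolog
RAB11FIP	RAB11 family interacting protein 3 and 4 (class II)
RADIL	Ras association and DIL domains/Ras interacting protein	B. floridae
RHBDF	Rhomboid 5 homolog
RHOT	Ras homolog gene family, member T1 and T2
RPH3A	Rabphilin 3A homolog/double C2-like domains, alpha
SDK	Sidekick cell adhesion molecule	C. elegans
SOX	Sex-determining region Y-box 8, 9 and 10
TEX2	Testis expressed 2
TNRC6	Trinucleotide repeat containing 6
TOM1	Target of myb1
TTYH	Tweety homolog
USP	Ubiquitin specific peptidase 31 and 43
WFIKKN	WAP, follistatin/kazal, immunoglobulin, kunitz and netrin domain contaning	B. floridae
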