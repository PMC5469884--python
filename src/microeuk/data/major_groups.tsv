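# Ordered substring -> major-group mapping (PR2-style lineages, case-insensitive).
# First matching pattern wins, so MALV-II must precede MALV-I and MAST uses the
# clade prefix "mast-" to avoid matching e.g. Mastigamoeba. Edit freely: PR2
# rank spellings vary between database versions.
# pattern	major_group
malv-ii	MALV-II
malv-i	MALV-I
cercozoa	Cercozoa
acantharea	Acantharea
polycystinea	Polycystinea
rad-b	RAD-B
ciliophora	Ciliophora
dinophyceae	Dinophyceae
bacillariophyta	Bacillariophyta
chrysophyceae	Photosynthetic Stramenopiles
synurophyceae	Photosynthetic Stramenopiles
dictyochophyceae	Photosynthetic Stramenopiles
pelagophyceae	Photosynthetic Stramenopiles
mast-	MAST
amoebozoa	Amoebozoa
archaeplastida	Archaeplastida
choanofla	Choanoflagellatea
fungi	Fungi
excavata	Excavata
hacrobia	Hacrobia
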