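# Default library-design preset.
#
# The docking sequence is the reverse complement of the biotinylated capture
# oligonucleotide (5'-CGTTCTGTGTCTTTCGTCGAT-3') used to pull down RNA-phage
# complexes in the second purification step.  The scaffold amino-acid
# sequence and the fixed RNA flanks are SYNTHETIC stand-ins (the real
# sequences are not part of this package); the randomized residue positions
# (34, 37, 40, 88-92) follow the L7Ae-scaffold library design.
rna_library:
  fixed_5p: GGGAAUGGAUCCACAUCUACGAAUUC
  variable_length: 20
  fixed_3p: UUCGACAGGAUCGACGAAAGACACAGAACG
  docking_sequence: AUCGACGAAAGACACAGAACG
protein_library:
  scaffold: MSVKEALNRAQGTKDLVKGIAQGVAEGKLTVEDLEVKLNRSTAELGKVIADNLGVPVAEVRGLSAEQQRELAEKLGSLDVIEGRLIGEGIVKAVE
  randomized_positions: [34, 37, 40, 88, 89, 90, 91, 92]
  codon_scheme: NNK
  read_window: [34, 92]
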