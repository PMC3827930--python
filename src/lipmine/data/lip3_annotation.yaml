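# Reference annotation for Candida rugosa Lip3 (mature-chain, 1-based).
#
# These positions are the editable defaults used for annotation transfer.
# Numbering conventions for the motif anchors differ between sources
# (precursor vs mature chain, motif start vs catalytic residue); the
# values below are mature-chain motif starts, consistent with the
# classical mature numbering of the family (catalytic Ser 209, Glu 341,
# His 449; lid delimited by the Cys 60 - Cys 97 disulfide).  The
# precursor-numbering equivalents (signal peptide of 15 residues) are the
# mature positions plus 15: GESAG start 222, GGGF start 137.
#
# load_reference_annotation() validates these positions against the
# reference sequence you pass to transfer_annotation(); edit this file if
# your reference uses a different numbering.
reference_id: Lip3
gggf_start: 122
gesag_start: 207
ser: 209
glu: 341
his: 449
cys_pair: [60, 97]
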