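# SYNTHETIC rule base for the type-2-diabetes running example.
# Test data authored for this package (not a real disease rule catalogue):
# constructed so that the premises MP_SMB and MP_CTM entail exactly the four
# pathways MP_TRXN, MP_ATM, MP_RRR and MP_TRAN.
R1: MP_SMB & MP_CTM -> MP_TRXN
R2: MP_TRXN -> MP_ATM
R3: MP_ATM & MP_CTM -> MP_RRR
R4: MP_RRR | MP_Q -> MP_TRAN
R5: MP_Z -> MP_Q
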