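whitelist_name,engine_name
nHBAcc,NumHAcceptors
nHBDon,NumHDonors
BCUTc-1l,BCUT2D_CHGLO
BCUTc-1h,BCUT2D_CHGHI
MAXDP,MaxEStateIndex
MAXDN,MinEStateIndex
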