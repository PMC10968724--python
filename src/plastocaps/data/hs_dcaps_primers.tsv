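name	sequence
Hs_dCAPS_F	ATGCAAAATCTATTTATATGAAAAATAAAAAGC
Hs_dCAPS_R	AATCAGTTTTTCAAAAGATTTATCAGACA
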