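caf_signature	cancer-associated fibroblast marker signature	FAP	PDGFRB	ACTA2	THY1	COL1A1	COL1A2	PDPN	ZEB1
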