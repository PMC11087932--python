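chr9	21967751	22009280	CDKN2AB
chr7	55086714	55324313	EGFR
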