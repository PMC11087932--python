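chr9	21967752	22009313	CDKN2AB
chr7	55019017	55211628	EGFR
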