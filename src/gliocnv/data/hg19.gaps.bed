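chr1	121535434	124535434	centromere
chr2	92326171	95326171	centromere
chr3	90504854	93504854	centromere
chr4	49660117	52660117	centromere
chr5	46405641	49405641	centromere
chr6	58830166	61830166	centromere
chr7	58054331	61054331	centromere
chr8	43838887	46838887	centromere
chr9	47367679	50367679	centromere
chr10	39254935	42254935	centromere
chr11	51644205	54644205	centromere
chr12	34856694	37856694	centromere
chr13	16000000	19000000	centromere
chr14	16000000	19000000	centromere
chr15	17000000	20000000	centromere
chr16	35335801	38335801	centromere
chr17	22263006	25263006	centromere
chr18	15460898	18460898	centromere
chr19	24681782	27681782	centromere
chr20	26369569	29369569	centromere
chr21	11288129	14288129	centromere
chr22	13000000	16000000	centromere
chrX	58632012	61632012	centromere
chrY	10104553	13104553	centromere
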