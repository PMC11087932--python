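chr1	121700000	125100000	centromere
chr2	91800000	96000000	centromere
chr3	87800000	94000000	centromere
chr4	48200000	51800000	centromere
chr5	46100000	51400000	centromere
chr6	58500000	62600000	centromere
chr7	58100000	62100000	centromere
chr8	43200000	47200000	centromere
chr9	42200000	45500000	centromere
chr10	38000000	41600000	centromere
chr11	51000000	55800000	centromere
chr12	33200000	37800000	centromere
chr13	16500000	18900000	centromere
chr14	16100000	18200000	centromere
chr15	17500000	20500000	centromere
chr16	35300000	38400000	centromere
chr17	22700000	27400000	centromere
chr18	15400000	21500000	centromere
chr19	24200000	28100000	centromere
chr20	25700000	30400000	centromere
chr21	10900000	13000000	centromere
chr22	13700000	17400000	centromere
chrX	58100000	63800000	centromere
chrY	10300000	10600000	centromere
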