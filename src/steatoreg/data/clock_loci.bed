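chr4	141251014	141251016	Arhgef19	0	+
chr15	11383945	11383947	Tars	0	+
chr9	85324736	85324738	Tent5a	0	+
chr15	76457711	76457713	Scx	0	+
chr6	94667252	94667254	Lrig1	0	+
chr5	33729706	33729708	Fgfr3	0	+
chr16	30260866	30260868	Cpn2	0	-
chr1	73959152	73959154	Tns1	0	-
chr14	51908371	51908373	Ndrg2	0	-
chr19	26640520	26640522	Smarca2	0	+
chr5	92364788	92364790	Art3	0	+
chr4	154557098	154557100	Prdm16	0	-
chr7	139559948	139559950	Inpp5a	0	+
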