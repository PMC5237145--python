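gene_id	rnaseq_fold	qpcr_fold
MYH15	9.2	5.1
TPM3	2.3	2.2
MYOZ2	5.9	4.4
TNNI1	5.7	24.7
MSTN	2.2	1.4
PLN	13.8	-2.4
PPARGC1A	-2.2	-1.5
PPARGC1B	-2.3	-1.7
FABP4	6.5	5.0
CKMT1A	1.6	1.3
MB	10.9	10.3
LMOD2	32.2	-1.1
CA3	30.3	4.6
NOXO1	18.1	1.2
MYBPC1	12.6	10.8
IL23R	-13.4	1.2
GPM6A	-11.4	-1.7
PPDPF	-6.5	-5.3
ACE	-6.0	1.1
CD9	-5.9	-4.5
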