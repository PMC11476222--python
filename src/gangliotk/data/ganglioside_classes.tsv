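class	hex	hexnac	neuac	sulfate	phosphate	has_acyl	isomer_group	elution_note
Cer	0	0	0	0	0	1
CerP	0	0	0	0	1	1
Hex1Cer	1	0	0	0	0	1
Hex2Cer	2	0	0	0	0	1
Hex3Cer	3	0	0	0	0	1
GM3	2	0	1	0	0	1
GM2	2	1	1	0	0	1
GM1	3	1	1	0	0	1	GM1a,GM1b
GD3	2	0	2	0	0	1
GD2	2	1	2	0	0	1
GD1	3	1	2	0	0	1	GD1a,GD1b	GD1a elutes before GD1b on ZIC-HILIC
GT3	2	0	3	0	0	1
GT2	2	1	3	0	0	1
GT1	3	1	3	0	0	1	GT1a,GT1b,GT1c
GQ1	3	1	4	0	0	1	GQ1b,GQ1c
GA2	2	1	0	0	0	1
GA1	3	1	0	0	0	1
ST	1	0	0	1	0	1
SPHP	0	0	0	0	1	0
CerG2GNAc1	2	1	0	0	0	1
CerG3GNAc2	3	2	0	0	0	1
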