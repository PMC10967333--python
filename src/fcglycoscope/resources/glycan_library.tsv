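shorthand	hexnac	hex	fuc	neuac	class_override
monoHexNAc	1	0	0	0
	2	3	0	0
	2	3	1	0
	2	4	0	0
Man5	2	5	0	0
Man6	2	6	0	0
Man7	2	7	0	0
Man8	2	8	0	0
Man9	2	9	0	0
	3	3	0	0
	3	3	1	0
	3	4	0	0
	3	4	1	0
	3	5	0	0
	3	5	1	0
	3	6	0	0
	3	6	1	0
	3	7	0	0
G0	4	3	0	0
G0F	4	3	1	0
G1	4	4	0	0
G1F	4	4	1	0
G2	4	5	0	0
G2F	4	5	1	0
G1S1	4	4	0	1
G1S1F	4	4	1	1
G2S1	4	5	0	1
G2S1F	4	5	1	1
G2S2	4	5	0	2
G2S2F	4	5	1	2
	5	3	0	0
	5	3	1	0
	5	4	0	0
	5	4	1	0
	5	5	0	0
	5	5	1	0
	5	6	1	0
	6	3	1	0
	4	6	0	0
	4	6	1	1
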