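taxon	series	mono_mz	diagnostic
Mammalia	P1105	1105.6	0
Mammalia	P1706	1706.7	0
Carnivora/Sus scrofa/Lepus sp.	C	1453.7	1
Ungulata	U1	2215.1	1
Ungulata	U2	2391.2	1
Cervidae	C1	1550.8	1
Cervidae	C2	2501.3	1
Bos primigenius	B	1192.5	1
Bos primigenius	D	2131.2	1
Bos primigenius	E	2792.4	1
Bos primigenius	F	3093.5	1
Bison priscus	B	1192.5	1
Bison priscus	D	2131.2	1
Bison priscus	E	2792.4	1
Bison priscus	F	3093.5	1
Cervus elaphus	B	1180.6	1
Cervus elaphus	D	2163.3	1
Cervus elaphus	E	2810.5	1
Cervus elaphus	F	3021.4	1
Capreolus capreolus	B	1166.6	1
Capreolus capreolus	D	2175.4	1
Capreolus capreolus	E	2834.6	1
Capreolus capreolus	F	2957.3	1
Caprinae	B	1197.5	1
Caprinae	D	2139.9	1
Caprinae	E	2883.4	1
Caprinae	F	3077.1	1
Equus ferus	B	1211.7	1
Equus ferus	D	2145.1	1
Equus ferus	E	2860.6	1
Equus ferus	F	3157.6	1
Sus scrofa	B	1223.7	1
Sus scrofa	D	2187.5	1
Sus scrofa	E	2905.7	1
Sus scrofa	F	3187.7	1
Canis lupus	B	1235.8	1
Canis lupus	D	2199.6	1
Canis lupus	E	2917.8	1
Canis lupus	F	3203.8	1
Vulpes vulpes	B	1247.8	1
Vulpes vulpes	D	2211.7	1
Vulpes vulpes	E	2929.9	1
Vulpes vulpes	F	3219.9	1
Ursus sp.	B	1259.9	1
Ursus sp.	D	2223.8	1
Ursus sp.	E	2941.0	1
Ursus sp.	F	3235.0	1
Lynx lynx	B	1259.9	1
Lynx lynx	D	2223.8	1
Lynx lynx	E	2941.0	1
Lynx lynx	F	3235.0	1
Felis silvestris	B	1259.9	1
Felis silvestris	D	2223.8	1
Felis silvestris	E	2953.1	1
Felis silvestris	F	3251.1	1
Lepus sp.	B	1272.0	1
Lepus sp.	D	2247.9	1
Lepus sp.	E	2977.2	1
Lepus sp.	F	3267.2	1
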