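index	name	development_history	flower_color	country	maternal_hsvm	sequence
1	HSVM	Regional variety	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
2	HS 'Andong'	HSVM graft mutation	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
3	HS 'Lil Kim'	HSVM graft mutation	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
4	HS 'Suni'	HS 'Helene' x HS 'Asadal'	White with spot	South Korea	no	CACTCCATA---GTCTGATA
5	HS 'Simsan'	HS 'Helene' x HS 'Mauve Queen'	White with spot	South Korea	no	CACTCCATA---GTCTGATA
6	HS 'Wonwha'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
7	HS 'Ggoma'	Radiation breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
8	HS 'Tanshim'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
9	HS 'Baekdanshim'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
10	HS 'Byeollee'	HS 'Gaeryangdanshim' x (HS 'Baekdanshim' x HSVM)	White with spot	South Korea	no	CACTCCATA---GTCTGATA
11	HS 'Simbaek'	HS 'Hwahap' x HS 'Samchulri'	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
12	HS 'Hairi'	HS 'Andong' x HS 'Hwahap'	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
13	HS 'Saebit'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
14	HS 'Sondok'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
15	HS 'Hanmaum'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
16	HS 'Hanbit'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
17	HS 'Hanyang'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
18	HS 'Hanoltanshim'	Selection breeding	White with spot	South Korea	no	CACTCCATA---GTCTGATA
19	HS 'Pheasant Eye'	Introduction breeding	White with spot	United states	no	CACTCCATA---GTCTGATA
20	HS 'Hinomaru'	Exotic cultivar	White with spot	Japan	no	CACTCCATA---GTCTGATA
21	HS 'Byeonghwa'	HS 'Andong' x HS 'Bulsae'	Purple with spot	South Korea	yes	CACTCCATAATAGTCTGATA
22	HS 'Cheoyong'	HS 'Andong' x HS 'Gaeryangjaju1'	Purple with spot	South Korea	yes	CACTCCATAATAGTCTGATA
23	HS 'Chungam'	HS 'Andong' x HS 'Gaeryangjaju1'	Purple with spot	South Korea	yes	CACTCCATAATAGTCTGATA
24	HS 'Taewha'	HS 'Cheoyong' x HS 'Gwangmyoung'	Purple with spot	South Korea	yes	CACTCCATAATAGTCTGATA
25	HS N.M. no. 520	Designated as a natural monument no. 520	Purple with spot	South Korea	no	CACTCCATA---GTCTGATA
26	HS N.M. no. 521	Designated as a natural monument no. 521	Purple with spot	South Korea	no	CACTCCATA---GTCTGATA
27	HS 'Tamra'	Selection breeding	Purple with spot	South Korea	no	CACTCCATA---GTCTGATA
28	HS 'Soyang'	Selection breeding	Purple with spot	South Korea	no	CACTCCATA---GTCTGATA
29	HS 'Ishigakijima'	Exotic cultivar	Purple with spot	Japan	no	CACTCCATA---GTCTGATA
30	HS 'Heikeyama'	Exotic cultivar	Purple with spot	Japan	no	CACTCCATA---GTCTGATA
31	HS 'Campanha'	Exotic cultivar	White with spot	United states	no	CACTCCATA---GTCTGATA
32	HS 'Helene'	Exotic cultivar	White with spot	United states	no	CACTCCATA---GTCTGATA
33	HS 'Dorothy Crane'	Exotic cultivar	White with spot	England	no	CACTCCATA---GTCTGATA
34	HS 'Mostrosus'	Exotic cultivar	White with spot	Belgium	no	CACTCCATA---GTCTGATA
35	HS 'Shiroshorin'	Exotic cultivar	White with spot	Japan	no	CACTCCATA---GTCTGATA
36	HS 'Blue Bird'	Exotic cultivar	Blue with spot	United states/France	no	CACTCCATA---GTCTGATA
37	HS 'Shigyoku'	Exotic cultivar	Blue with spot	Japan	no	CACTCCATA---GTCTGATA
38	HS 'Oknyo'	Selection breeding	White without spot	South Korea	no	CACTCCATA---GTCTGATA
39	HS 'Saehan'	Selection breeding	White without spot	South Korea	no	CACTCCATA---GTCTGATA
40	HS 'Wood Bridge'	Exotic cultivar	Red with spot	England	no	CACTCCATA---GTCTGATA
41	HS 'Akagionmamori'	Exotic cultivar	Red with spot	Japan	no	CACTCCATA---GTCTGATA
42	HS 'Yaum'	HS 'Andong' x HS 'Samchulri'	Purple with spot	South Korea	yes	CACTCCATAATAGTCTGATA
43	HS 'Hwahap'	HS 'Andong' x HS 'Namwon'	White with spot	South Korea	yes	CACTCCATAATAGTCTGATA
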