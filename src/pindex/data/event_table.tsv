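event_number	event_name	printed_nature	checked_genome	reference_genome	pindex_value
1	Brassica-common hexaploidy	Allo	B. oleracea	A. thaliana	0.85
1	Brassica-common hexaploidy	Allo	B. rapa	A. thaliana	0.82
2	B. napus-specific tetraploidy	Allo	B. napus	B. rapa	0.78
2	B. napus-specific tetraploidy	Allo	B. napus	B. oleracea	0.76
3	Arabidopsis tetraploid 1	unlabeled	A. thaliana	V. vinifera	0.34
3	Arabidopsis tetraploid 1	unlabeled	A. lyrata	V. vinifera	0.36
4	Arabidopsis tetraploid 2	unlabeled	A. thaliana	V. vinifera	0.41
4	Arabidopsis tetraploid 2	unlabeled	A. lyrata	V. vinifera	0.50
5	Solanaceae-common hexaploidy	Allo	S. lycopersicum	C. canephora	0.53
5	Solanaceae-common hexaploidy	Allo	S. tuberosum	C. canephora	0.56
5	Solanaceae-common hexaploidy	Allo	C. annuum	C. canephora	0.50
5	Solanaceae-common hexaploidy	Allo	C. annuum	V. vinifera	0.48
5	Solanaceae-common hexaploidy	Allo	S. melongena	C. canephora	0.47
6	Gossypodium-common decaploidy	Allo	G. raimondii	T. cacao	0.47
6	Gossypodium-common decaploidy	Allo	G. raimondii	V. vinifera	0.57
6	Gossypodium-common decaploidy	Allo	G. arboreum	T. cacao	0.42
6	Gossypodium-common decaploidy	Allo	G. arboreum	V. vinifera	0.51
7	Gossypium tetraploidy	Allo	G. hirsutum	G. raimondii	0.70
8	Fabaceae-common tetraploidy	Allo	M. truncatula	V. vinifera	0.39
8	Fabaceae-common tetraploidy	Allo	V. radiata	V. vinifera	0.45
8	Fabaceae-common tetraploidy	Allo	V. angularis	V. vinifera	0.49
8	Fabaceae-common tetraploidy	Allo	C. arietium	V. vinifera	0.42
8	Fabaceae-common tetraploidy	Allo	P. vulgaris	V. vinifera	0.42
8	Fabaceae-common tetraploidy	Allo	L. japonicus	V. vinifera	0.50
8	Fabaceae-common tetraploidy	Allo	C. cajan	V. vinifera	0.36
8	Fabaceae-common tetraploidy	Allo	A. ipaensis	V. vinifera	0.48
8	Fabaceae-common tetraploidy	Allo	A. duranensis	V. vinifera	0.51
9	Soybean-specific tetraploidy	Auto	G. max	M. truncatula	0.17
10	Cucurbitaceae-common tetraploidy	Allo	C. lanatus	V. vinifera	0.38
10	Cucurbitaceae-common tetraploidy	Allo	C. sativus L.	V. vinifera	0.56
10	Cucurbitaceae-common tetraploidy	Allo	C. melo L.	V. vinifera	0.67
11	Apple-specific autotetraploidy	Auto	M. domestica	P. persica	0.22
11	Apple-specific autotetraploidy	Auto	M. domestica	P. mume	0.22
12	Poplar-specific autotetraploidy	Auto	P. trichocarpa	P. persica	0.26
13	Major eudicot-common hexaploidy	Allo	V. vinifera	V. vinifera	0.79
14	Grass-common tetraploidy	Allo	O. sativa	A. comosus	0.43
14	Grass-common tetraploidy	Allo	S. bicolor	A. comosus	0.41
14	Grass-common tetraploidy	Allo	S. italica	A. comosus	0.44
14	Grass-common tetraploidy	Allo	B. distachyon	A. comosus	0.39
15	Zea-specific tetraploidy	Allo	Z. mays	O. sativa	0.84
15	Zea-specific tetraploidy	Allo	Z. mays	S. italica	0.69
15	Zea-specific tetraploidy	Allo	Z. mays	S. bicolor	0.71
16	Triticum-specific hexaploidy	Allo	T. aestivum	A. tauschii	0.42
16	Triticum-specific hexaploidy	Allo	T. aestivum	T. urartu	0.43
16	Triticum-specific hexaploidy	Allo	T. aestivum-1	H. vulgare	0.75
16	Triticum-specific hexaploidy	Allo	T. aestivum-2	H. vulgare	0.52
17	Ananas tetraploidy	Allo	A. comosus	E. guineensis	0.39
17	Ananas tetraploidy	Allo	A. comosus	S. polyrhiza	0.44
17	Ananas tetraploidy	Allo	A. comosus	V. vinifera	0.42
18	Elaeis-specific tetraploidy	Allo	E. guineensis	A. comosus	0.58
18	Elaeis-specific tetraploidy	Allo	E. guineensis	S. polyrhiza	0.50
19	Commelinids-common tetraploidy	Allo	E. guineensis	S. polyrhiza	0.50
20	S. polyrhiza tetraploidy 1	Allo	S. polyrhiza	V. vinifera	0.47
21	S. polyrhiza tetraploidy 2	Allo	S. polyrhiza	V. vinifera	0.44
22	Musa tetraploidy 1	Allo	M. acuminata	E. guineensis	0.37
23	Musa tetraploidy 2	Allo	M. acuminata	E. guineensis	0.35
24	Musa tetraploidy 3	Allo	M. acuminata	E. guineensis	0.44
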