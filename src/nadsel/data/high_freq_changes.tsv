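gene	ref_aa	alt_aa	protein_pos	frequency
NRK	V	M	358	0.31
NADK	N	K	262	0.28
NT5E	T	A	376	0.76
PNP	G	S	51	0.22
ART1	L	P	257	0.55
ART3	S	L	341	0.47
ART4	D	N	265	0.28
PARP13	H	Q	565	0.26
PARP13	R	K	485	0.25
PARP15	G	R	628	0.23
PARP4	A	P	1656	0.42
PARP4	P	T	1328	0.38
PARP4	G	R	1280	0.38
PARP4	G	A	1265	0.38
PARP4	V	A	1065	0.64
PARP4	A	T	899	0.66
PARP4	S	N	873	0.23
PARP9	Y	C	528	0.54
PARP10	V	A	630	0.54
PARP10	L	P	395	0.35
PARP10	I	V	249	0.38
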