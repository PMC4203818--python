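allele	-1584	31	100	1023	1846	2549	2615	2850	2988	3183	4180	multiplier	activity
*1	C	G	C	C	G	A	A	C	G	G	G	1	Normal
*2	G	G	C	C	G	A	A	T	G	G	C	1	Normal
*3	C	G	C	C	G	del	A	C	G	G	G	1	None
*4	C	G	T	C	A	A	A	C	G	G	C	1	None
*5	-	-	-	-	-	-	-	-	-	-	-	1	None
*9	C	G	C	C	G	A	del	C	G	G	G	1	Decr
*10	C	G	T	C	G	A	A	C	G	G	C	1	Decr
*17	C	G	C	T	G	A	A	T	G	G	C	1	Decr
*29	C	G	C	C	G	A	A	T	G	A	C	1	Decr
*34	C	G	C	C	G	A	A	T	G	G	G	1	ND
*35	G	A	C	C	G	A	A	T	G	G	C	1	Normal
*39	C	G	C	C	G	A	A	C	G	G	C	1	Normal
*41	C	G	C	C	G	A	A	T	A	G	C	1	Decr
*1x2	C	G	C	C	G	A	A	C	G	G	G	2	Incr
*1x3	C	G	C	C	G	A	A	C	G	G	G	3	Incr
*2x2	G	G	C	C	G	A	A	T	G	G	C	2	Incr
*2x5	G	G	C	C	G	A	A	T	G	G	C	5	Incr
*4x2	C	G	T	C	A	A	A	C	G	G	C	2	None
*17x2	C	G	C	T	G	A	A	T	G	G	C	2	ND
*35x2	G	A	C	C	G	A	A	T	G	G	C	2	Incr
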