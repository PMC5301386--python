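task	kind	state	type	type2	count
epitope	single	E	A	.	1
epitope	single	E	C	.	1
epitope	single	E	D	.	6
epitope	single	E	E	.	5
epitope	single	E	F	.	2
epitope	single	E	I	.	1
epitope	single	E	K	.	7
epitope	single	E	L	.	1
epitope	single	E	M	.	1
epitope	single	E	N	.	3
epitope	single	E	P	.	3
epitope	single	E	Q	.	2
epitope	single	E	R	.	5
epitope	single	E	S	.	1
epitope	single	E	W	.	1
epitope	single	E	Y	.	1
epitope	single	N	A	.	10
epitope	single	N	C	.	7
epitope	single	N	D	.	8
epitope	single	N	E	.	6
epitope	single	N	F	.	4
epitope	single	N	G	.	9
epitope	single	N	H	.	9
epitope	single	N	I	.	2
epitope	single	N	K	.	5
epitope	single	N	L	.	5
epitope	single	N	M	.	4
epitope	single	N	N	.	3
epitope	single	N	P	.	3
epitope	single	N	Q	.	1
epitope	single	N	R	.	4
epitope	single	N	S	.	4
epitope	single	N	T	.	3
epitope	single	N	V	.	3
epitope	single	N	W	.	5
epitope	single	N	Y	.	2
epitope	pair	E	A	E	1
epitope	pair	E	A	N	1
epitope	pair	E	C	D	1
epitope	pair	E	C	E	1
epitope	pair	E	D	E	3
epitope	pair	E	D	F	2
epitope	pair	E	D	K	4
epitope	pair	E	D	R	1
epitope	pair	E	E	F	1
epitope	pair	E	E	K	1
epitope	pair	E	E	N	2
epitope	pair	E	E	Y	1
epitope	pair	E	F	K	1
epitope	pair	E	I	K	1
epitope	pair	E	I	L	1
epitope	pair	E	K	L	1
epitope	pair	E	K	M	1
epitope	pair	E	K	P	1
epitope	pair	E	K	R	3
epitope	pair	E	M	R	1
epitope	pair	E	N	P	1
epitope	pair	E	N	Q	1
epitope	pair	E	N	Y	1
epitope	pair	E	P	Q	1
epitope	pair	E	P	R	2
epitope	pair	E	P	W	1
epitope	pair	E	Q	R	1
epitope	pair	E	Q	S	1
epitope	pair	E	R	S	1
epitope	pair	E	R	W	1
epitope	pair	N	A	C	4
epitope	pair	N	A	D	2
epitope	pair	N	A	E	3
epitope	pair	N	A	F	2
epitope	pair	N	A	G	3
epitope	pair	N	A	H	1
epitope	pair	N	A	K	1
epitope	pair	N	A	L	2
epitope	pair	N	A	N	1
epitope	pair	N	C	D	1
epitope	pair	N	C	E	1
epitope	pair	N	C	G	3
epitope	pair	N	C	H	3
epitope	pair	N	D	D	2
epitope	pair	N	D	F	1
epitope	pair	N	D	K	1
epitope	pair	N	D	R	3
epitope	pair	N	D	S	3
epitope	pair	N	D	T	1
epitope	pair	N	E	F	1
epitope	pair	N	E	G	1
epitope	pair	N	E	K	1
epitope	pair	N	E	L	2
epitope	pair	N	E	W	1
epitope	pair	N	E	Y	1
epitope	pair	N	F	G	2
epitope	pair	N	F	H	1
epitope	pair	N	F	L	1
epitope	pair	N	G	H	6
epitope	pair	N	G	I	1
epitope	pair	N	G	N	1
epitope	pair	N	G	W	1
epitope	pair	N	H	I	2
epitope	pair	N	H	K	1
epitope	pair	N	H	P	1
epitope	pair	N	H	W	2
epitope	pair	N	I	K	1
epitope	pair	N	K	L	1
epitope	pair	N	K	M	2
epitope	pair	N	K	R	1
epitope	pair	N	L	M	2
epitope	pair	N	L	N	1
epitope	pair	N	M	N	2
epitope	pair	N	M	P	1
epitope	pair	N	N	P	1
epitope	pair	N	P	Q	1
epitope	pair	N	P	R	1
epitope	pair	N	P	W	1
epitope	pair	N	Q	R	1
epitope	pair	N	R	S	1
epitope	pair	N	S	T	2
epitope	pair	N	S	V	1
epitope	pair	N	T	V	2
epitope	pair	N	T	W	1
epitope	pair	N	V	W	2
epitope	pair	N	V	Y	1
epitope	pair	N	W	Y	2
exposure	single	B	A	.	7
exposure	single	B	C	.	6
exposure	single	B	D	.	1
exposure	single	B	E	.	2
exposure	single	B	F	.	2
exposure	single	B	G	.	5
exposure	single	B	H	.	5
exposure	single	B	I	.	1
exposure	single	B	L	.	3
exposure	single	B	M	.	1
exposure	single	B	N	.	1
exposure	single	B	S	.	1
exposure	single	B	T	.	2
exposure	single	B	V	.	3
exposure	single	B	W	.	2
exposure	single	B	Y	.	1
exposure	single	E	A	.	4
exposure	single	E	C	.	2
exposure	single	E	D	.	13
exposure	single	E	E	.	9
exposure	single	E	F	.	4
exposure	single	E	G	.	4
exposure	single	E	H	.	4
exposure	single	E	I	.	2
exposure	single	E	K	.	12
exposure	single	E	L	.	3
exposure	single	E	M	.	4
exposure	single	E	N	.	5
exposure	single	E	P	.	6
exposure	single	E	Q	.	3
exposure	single	E	R	.	9
exposure	single	E	S	.	4
exposure	single	E	T	.	1
exposure	single	E	W	.	4
exposure	single	E	Y	.	2
exposure	pair	B	A	C	4
exposure	pair	B	A	D	1
exposure	pair	B	A	E	2
exposure	pair	B	A	F	1
exposure	pair	B	A	G	2
exposure	pair	B	A	H	1
exposure	pair	B	A	L	2
exposure	pair	B	C	D	1
exposure	pair	B	C	E	1
exposure	pair	B	C	G	2
exposure	pair	B	C	H	2
exposure	pair	B	E	L	1
exposure	pair	B	F	G	1
exposure	pair	B	F	H	1
exposure	pair	B	F	L	1
exposure	pair	B	G	H	4
exposure	pair	B	G	I	1
exposure	pair	B	H	I	1
exposure	pair	B	L	M	1
exposure	pair	B	L	N	1
exposure	pair	B	M	N	1
exposure	pair	B	S	T	1
exposure	pair	B	S	V	1
exposure	pair	B	T	V	2
exposure	pair	B	T	W	1
exposure	pair	B	V	W	2
exposure	pair	B	V	Y	1
exposure	pair	B	W	Y	1
exposure	pair	E	A	D	1
exposure	pair	E	A	E	2
exposure	pair	E	A	F	1
exposure	pair	E	A	G	1
exposure	pair	E	A	K	1
exposure	pair	E	A	N	2
exposure	pair	E	C	D	1
exposure	pair	E	C	E	1
exposure	pair	E	C	G	1
exposure	pair	E	C	H	1
exposure	pair	E	D	D	2
exposure	pair	E	D	E	3
exposure	pair	E	D	F	3
exposure	pair	E	D	K	5
exposure	pair	E	D	R	4
exposure	pair	E	D	S	3
exposure	pair	E	D	T	1
exposure	pair	E	E	F	2
exposure	pair	E	E	G	1
exposure	pair	E	E	K	2
exposure	pair	E	E	L	1
exposure	pair	E	E	N	2
exposure	pair	E	E	W	1
exposure	pair	E	E	Y	2
exposure	pair	E	F	G	1
exposure	pair	E	F	K	1
exposure	pair	E	G	H	2
exposure	pair	E	G	N	1
exposure	pair	E	G	W	1
exposure	pair	E	H	I	1
exposure	pair	E	H	K	1
exposure	pair	E	H	P	1
exposure	pair	E	H	W	2
exposure	pair	E	I	K	2
exposure	pair	E	I	L	1
exposure	pair	E	K	L	2
exposure	pair	E	K	M	3
exposure	pair	E	K	P	1
exposure	pair	E	K	R	4
exposure	pair	E	L	M	1
exposure	pair	E	M	N	1
exposure	pair	E	M	P	1
exposure	pair	E	M	R	1
exposure	pair	E	N	P	2
exposure	pair	E	N	Q	1
exposure	pair	E	N	Y	1
exposure	pair	E	P	Q	2
exposure	pair	E	P	R	3
exposure	pair	E	P	W	2
exposure	pair	E	Q	R	2
exposure	pair	E	Q	S	1
exposure	pair	E	R	S	2
exposure	pair	E	R	W	1
exposure	pair	E	S	T	1
exposure	pair	E	W	Y	1
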