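#argkit	earg	1
#L	10.0
#V	id	kind	breakpoint	time	metadata
#E	child	parent	side
V	0	S		0.0	a
V	1	S		0.0	b
V	2	S		0.0	c
V	3	R	7.0	1.0	d
V	4	R	4.0	1.5	e
V	5	R	7.0	2.0	f
V	6	R	5.0	3.0	g
V	7	R	7.0	2.5	h
V	8	R	2.0	3.5	i
V	9	C		10.0	j
V	10	C		7.0	k
V	11	C		4.0	l
V	12	C		5.0	m
V	13	C		6.0	n
V	14	C		8.0	o
V	15	C		9.0	p
V	16	C		11.0	q
E	0	3	only
E	1	4	only
E	2	7	only
E	3	8	left
E	3	14	right
E	4	5	right
E	4	6	left
E	5	13	left
E	5	14	right
E	6	9	right
E	6	11	left
E	7	10	left
E	7	15	right
E	8	11	left
E	8	12	right
E	9	16	only
E	10	9	only
E	11	12	only
E	12	13	only
E	13	10	only
E	14	15	only
E	15	16	only
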