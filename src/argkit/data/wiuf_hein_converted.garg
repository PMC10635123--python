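#argkit	garg	1
#L	10.0
#N	id	is_sample	time	metadata
#E	child	parent	left	right
N	0	1	0.0	a
N	1	1	0.0	b
N	2	1	0.0	c
N	3	0	1.0	d
N	4	0	1.5	e
N	5	0	2.0	f
N	6	0	3.0	g
N	7	0	2.5	h
N	8	0	3.5	i
N	9	0	10.0	j
N	10	0	7.0	k
N	11	0	4.0	l
N	12	0	5.0	m
N	13	0	6.0	n
N	14	0	8.0	o
N	15	0	9.0	p
N	16	0	11.0	q
E	0	3	0.0	10.0
E	1	4	0.0	10.0
E	2	7	0.0	10.0
E	3	8	0.0	7.0
E	3	14	7.0	10.0
E	4	5	4.0	10.0
E	4	6	0.0	4.0
E	5	13	0.0	7.0
E	5	14	7.0	10.0
E	6	9	5.0	10.0
E	6	11	0.0	5.0
E	7	10	0.0	7.0
E	7	15	7.0	10.0
E	8	11	0.0	2.0
E	8	12	2.0	10.0
E	9	16	0.0	10.0
E	10	9	0.0	10.0
E	11	12	0.0	10.0
E	12	13	0.0	10.0
E	13	10	0.0	10.0
E	14	15	0.0	10.0
E	15	16	0.0	10.0
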