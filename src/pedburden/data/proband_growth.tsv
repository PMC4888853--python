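case	sex	variant	hsds_4	hsds_8or9	th_sds	delta_hsds	dist_th_4y	dist_th_8or9	adult_hsds
1.II.1	male	p.Arg156Leu	-1.1	-1.3	-0.4	-0.2	0.7	0.9	-0.9
2.II.1	male	p.Arg156Leu	-0.2	-0.4	-0.7	-0.2	-0.5	-0.3	0.1
3.III.2	male	p.Glu161Lys	-0.5	-0.8	0.7	-0.3	1.2	1.5	-0.9
4.III.1	male	p.Glu161Lys	-0.4	-0.7	0.4	-0.3	0.8	1.1	0.0
5.II.1	male	p.Glu161Lys	-0.3	-0.2	0.9	0.1	1.2	1.1	0.9
6.II.1	male	p.Glu161Lys	-0.2	0.0	1.7	0.2	1.9	1.7	0.0
7.III.5	male	p.Asp2614Asn	-1.0	-1.5	-0.4	-0.5	0.6	1.1	-0.2
8.III.2	female	p.Asp2614Asn	-1.9	-2.2	-1.0	-0.3	0.9	1.2	-1.9
9.II.4	male	p.Asp2614Asn	-0.7	-1.6	-0.2	-0.9	0.5	1.4	-0.4
10.II.1	male	p.Glu2264Gly	-1.8	-2.0	-0.6	-0.2	1.2	1.4	-1.8
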