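row_id	marker	pop1_host	pop1_continent	pop2_host	pop2_continent	fst	dxy
U1	UBCie695	C	NA	R	NA	0.548	0.051
U2	UBCie695	C	NA	R	SA	0.509	0.056
U3	UBCie695	R	NA	C	SA	0.338	0.050
U4	UBCie695	C	SA	R	SA	0.310	0.054
U5	UBCie695	C	NA	C	SA	0.073	0.019
U6	UBCie695	R	NA	R	SA	0.110	0.049
T1	TpiEI194	C	NA	R	NA	0.559	0.126
T2	TpiEI194	C	NA	R	SA	0.391	0.113
T3	TpiEI194	R	NA	C	SA	0.572	0.130
T4	TpiEI194	C	SA	R	SA	0.407	0.116
T5	TpiEI194	C	NA	C	SA	-0.004	0.031
T6	TpiEI194	R	NA	R	SA	0.090	0.103
n1	nesEI533	C	NA	R	NA	0.682	0.027
n2	nesEI533	C	NA	R	SA	0.531	0.026
n3	nesEI533	R	NA	C	SA	0.645	0.027
n4	nesEI533	C	SA	R	SA	0.495	0.026
n5	nesEI533	C	NA	C	SA	0.010	0.003
n6	nesEI533	R	NA	R	SA	0.112	0.021
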