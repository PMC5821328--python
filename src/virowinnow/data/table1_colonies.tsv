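site	date	latitude	longitude	habitat	n_colonies	library
R	23-ix-14	-25.2875	-57.7054	Dike along river	7	SAL_1
S	22-ix-14	-25.3598	-57.6631	Dike	5	SAL_1
T	22-ix-14	-25.2948	-57.7445	Road right of way	8	SAL_1
U	24-ix-14	-25.3553	-58.2796	Low grass	9	SAL_1
V	24-ix-14	-25.1432	-58.2314	Roadside	9	SAL_1
W	24-ix-14	-25.2508	-57.9907	Roadside	8	SAL_1
A	16-ix-14	-26.6609	-58.6297	River bank, Costanera park	8	SAL_2
B	16-ix-14	-26.6222	-58.6653	Semi urban	9	SAL_2
C	17-ix-14	-26.5173	-58.2818	Field adjacent to road	9	SAL_2
D	17-ix-14	-26.4806	-58.2737	Marshy road area	7	SAL_2
E	17-ix-14	-26.4795	-58.3071	City park, mowed grass	9	SAL_2
F	17-ix-14	-26.3944	-58.3442	Gas station	7	SAL_2
X	25-ix-14	-26.5412	-58.5081	Roadside	1	SAL_2
Y	25-ix-14	-26.6474	-58.6236	Roadside	3	SAL_2
G	18-ix-14	-25.8786	-58.0872	Abandoned parking area and periphery	9	SAL_3
H	18-ix-14	-25.6733	-58.2561	Grassy roadside	6	SAL_3
N	20-ix-14	-26.1182	-58.2241	Urban, highly disturbed	5	SAL_3
O	22-ix-14	-26.1975	-58.2144	Adjacent to gas station	7	SAL_3
P	22-ix-14	-26.2281	-58.2405	Abandoned picnic area	9	SAL_3
Q	22-ix-14	-26.0416	-58.0589	Rural road side	8	SAL_3
I	19-ix-14	-26.2391	-58.6303	Rough grassy area	9	SAL_4
J	19-ix-14	-26.2050	-59.0708	City park	8	SAL_4
K	19-ix-14	-25.7411	-59.1021	Mowed road edge, west side	9	SAL_4
L	20-ix-14	-25.9357	-58.5124	Road edge	5	SAL_4
M	20-ix-14	-25.8637	-58.8858	Residential area	8	SAL_4
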