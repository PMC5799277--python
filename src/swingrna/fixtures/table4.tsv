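rule	n_454	mean_454	n_solid	mean_solid
A<->C	5	51.40	7261	35.52
A<->G	8	211.63	5294	36.47
A<->T	0		7234	35.99
C<->G	173	196.74	7314	35.92
C<->T	12	199.58	5800	36.29
G<->T	1	56.00	5553	35.63
A<->C-G<->T	0		2634	36.60
A<->G-C<->T	1	68.00	2672	36.37
A<->T-C<->G	0		1805	37.14
A->C->G->A	9	62.11	6238	35.73
A->C->T->A	1	64.00	4963	36.64
A->G->C->A	2	70.50	5013	36.68
A->G->T->A	1	79.00	6127	35.70
A->T->C->A	0		6325	35.97
A->T->G->A	0		4826	36.72
C->G->T->C	0		4856	36.68
C->T->G->C	9	52.67	5962	35.70
A->C->G->T->A	4	84.50	6007	36.28
A->C->T->G->A	1	77.00	8421	35.83
A->G->C->T->A	2	74.50	7675	35.45
A->G->T->C->A	0		8444	35.85
A->T->C->G->A	0		5289	35.71
A->T->G->C->A	0		5429	36.41
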