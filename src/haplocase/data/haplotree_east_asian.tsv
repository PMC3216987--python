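# Fixture haplogroup motif tree for the East-Asian mtDNA classes used in the
# case-control tables. One node per line: depth<TAB>name<TAB>comma-separated
# defining variant tokens ("!" suffix = back mutation to the reference state).
# Motifs are representative, not a redistribution of any published tree; users
# should supply their own tree file for production classification.
0	rCRS
1	M	263G,489C,10400T,16223T
2	M7	6455T,9824C,16209C
3	M7b	4164G,6680C,12811C,16297C
4	M7b1'2	5442C,16192T
5	M7b1	199C
5	M7b2	7853A,16189C
3	M7c	146C,4850T,16295T
2	M8	4715G,7196A,16298C
3	M8a	373G,6179A,16184T
3	CZ	249d,16288C
4	C	3552A,14318C
4	Z	6752G,16185T
2	M9	4491A,16234T
3	M9a	153G,16316G
2	M10	10646A,16311C
2	M12	5580C,16290T
2	G	4833G,5108C,16272C
2	D	4883T,5178A,16362C
3	D4	3010A,8414T,14668T
3	D5	150T,1107C,16189C
1	N	16519C
2	N9	5417A,16257A
3	N9a	16261T
3	Y	8392A,16231C
2	A	235G,663G,16290T,16319A
2	R	11719A
3	B4	499A,16217C
3	B5	210G,8584A,16140C
3	R9	3970T,13928C
4	F	249d,16304C
5	F1	6962A,16172C
6	F1a	16162G
5	F2	1005C,16203G
6	F2a	16167T
5	F3	3434G,16298C
6	F3a	16355T
5	F4	5263T,16249C
3	R11	1095C,16311C
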