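# Published minimum-origin counts per chromosome (base, mild 2/3-rate and
# harsh 1/3-rate stress scenarios), as printed; thirteen cells disagree with
# the exact ceiling formula and are errata-annotated in orimin.karyotype_io.
organism	chrom	mo	mo_mild	mo_harsh
tcruzi	I	1	1	1
tcruzi	II	1	1	1
tcruzi	III	1	1	1
tcruzi	IV	1	1	1
tcruzi	V	1	1	1
tcruzi	VI	1	1	1
tcruzi	VII	1	1	1
tcruzi	VIII	1	1	1
tcruzi	IX	1	1	1
tcruzi	X	1	1	1
tcruzi	XI	1	1	1
tcruzi	XII	1	1	1
tcruzi	XIII	1	1	1
tcruzi	XIV	1	1	1
tcruzi	XV	1	1	1
tcruzi	XVI	1	1	1
tcruzi	XVII	1	1	1
tcruzi	XVIII	1	1	1
tcruzi	XIX	1	1	1
tcruzi	XX	1	1	1
tcruzi	XXI	1	1	1
tcruzi	XXII	1	1	1
tcruzi	XXIII	1	1	1
tcruzi	XXIV	1	1	1
tcruzi	XXV	2	1	2
tcruzi	XXVI	1	1	1
tcruzi	XXVII	2	1	2
tcruzi	XXVIII	1	1	2
tcruzi	XXIX	1	1	2
tcruzi	XXX	1	1	2
tcruzi	XXXI	1	1	2
tcruzi	XXXII	1	1	2
tcruzi	XXXIII	1	1	2
tcruzi	XXXIV	1	1	2
tcruzi	XXXV	1	1	2
tcruzi	XXXVI	1	1	2
tcruzi	XXXVII	1	1	2
tcruzi	XXXVIII	1	1	2
tcruzi	XXXIX	1	2	2
tcruzi	XL	1	2	2
tcruzi	XLI	1	2	2
lmajor	I	1	1	1
lmajor	II	1	1	2
lmajor	III	1	1	2
lmajor	IV	1	1	2
lmajor	V	1	1	2
lmajor	VI	1	1	2
lmajor	VII	1	1	2
lmajor	VIII	1	1	2
lmajor	IX	1	1	2
lmajor	X	1	1	2
lmajor	XI	1	1	2
lmajor	XII	1	2	3
lmajor	XIII	1	2	3
lmajor	XIV	1	1	3
lmajor	XV	1	2	3
lmajor	XVI	1	2	3
lmajor	XVII	1	2	3
lmajor	XVIII	1	2	3
lmajor	XIX	1	2	3
lmajor	XX	1	2	3
lmajor	XXI	1	2	3
lmajor	XXII	1	2	3
lmajor	XXIII	1	2	3
lmajor	XXIV	1	2	3
lmajor	XXV	1	2	3
lmajor	XXVI	2	2	4
lmajor	XXVII	2	2	4
lmajor	XXVIII	2	2	4
lmajor	XXIX	2	2	4
lmajor	XXX	2	3	5
lmajor	XXXI	2	3	5
lmajor	XXXII	2	3	6
lmajor	XXXIII	2	3	6
lmajor	XXXIV	2	3	6
lmajor	XXXV	3	4	7
lmajor	XXXVI	3	5	9
tbrucei	I	2	2	4
tbrucei	II	2	3	5
tbrucei	III	2	3	6
tbrucei	IV	2	3	6
tbrucei	V	2	4	7
tbrucei	VI	2	3	6
tbrucei	VII	3	4	8
tbrucei	VIII	3	5	9
tbrucei	IX	4	7	13
tbrucei	X	5	8	15
tbrucei	XI	6	10	19
scerevisiae	I	3	4	8
scerevisiae	II	9	13	26
scerevisiae	III	4	5	10
scerevisiae	IV	16	24	48
scerevisiae	V	7	10	19
scerevisiae	VI	3	5	9
scerevisiae	VII	12	18	35
scerevisiae	VIII	6	9	18
scerevisiae	IX	5	7	14
scerevisiae	X	8	12	24
scerevisiae	XI	7	11	21
scerevisiae	XII	12	17	34
scerevisiae	XIII	10	15	30
scerevisiae	XIV	9	13	25
scerevisiae	XV	12	18	35
scerevisiae	XVI	10	15	30
spombe	I	129		
spombe	II	101		
spombe	III	57		
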