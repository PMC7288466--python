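# Trypanosoma cruzi nuclear karyotype (published reference assembly sizes)
# fork rate 2.05 kb/min, S-phase 591.6 min
chrom	length_bp
I	77958
II	151740
III	196644
IV	200401
V	227319
VI	389024
VII	391095
VIII	393423
IX	509634
X	518846
XI	526141
XII	533093
XIII	558364
XIV	598625
XV	612853
XVI	646207
XVII	648584
XVIII	655081
XIX	671453
XX	656799
XXI	704149
XXII	710778
XXIII	655477
XXIV	779922
XXV	822374
XXVI	801422
XXVII	850241
XXVIII	853233
XXIX	870934
XXX	863882
XXXI	947473
XXXII	968069
XXXIII	1041172
XXXIV	1065764
XXXV	1186946
XXXVI	1180744
XXXVII	1355803
XXXVIII	1444805
XXXIX	1854104
XL	2036760
XLI	2371736
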