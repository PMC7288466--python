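# Trypanosoma brucei nuclear karyotype (published reference assembly sizes)
# fork rate 3.06 kb/min, S-phase 138.6 min
chrom	length_bp
I	1064672
II	1193948
III	1653225
IV	1590432
V	1802303
VI	1618915
VII	2205233
VIII	2481190
IX	3542885
X	4144375
XI	5223313
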