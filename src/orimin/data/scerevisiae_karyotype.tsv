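# Saccharomyces cerevisiae nuclear karyotype (published reference assembly sizes)
# fork rate 1.6 kb/min, S-phase 30 min
chrom	length_bp
I	230190
II	813140
III	315340
IV	1522190
V	574860
VI	270150
VII	1090940
VIII	562640
IX	439880
X	745440
XI	666450
XII	1078170
XIII	924430
XIV	784330
XV	1091280
XVI	948060
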