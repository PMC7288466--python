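# Schizosaccharomyces pombe nuclear karyotype (published reference assembly sizes)
# fork rate 0.91 kb/min, S-phase 24 min
chrom	length_bp
I	5598923
II	4397795
III	2465919
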