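# Leishmania major nuclear karyotype (published reference assembly sizes)
# fork rate 2.44 kb/min, S-phase 192 min
chrom	length_bp
I	268988
II	355712
III	384502
IV	472852
V	465823
VI	516869
VII	596352
VIII	574960
IX	573434
X	570865
XI	582573
XII	675346
XIII	654595
XIV	622644
XV	629517
XVI	714651
XVII	684829
XVIII	739748
XIX	702208
XX	742537
XXI	772972
XXII	716602
XXIII	772565
XXIV	840950
XXV	912845
XXVI	1091540
XXVII	1130424
XXVIII	1160104
XXIX	1212663
XXX	1403434
XXXI	1484328
XXXII	1604637
XXXIII	1583653
XXXIV	1866748
XXXV	2090474
XXXVI	2682151
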