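index document: doc000
rank  patient      document       distance  relevant
   1  pat011       doc011         0.001732  yes
   2  pat002       doc002         0.001840  yes
   3  pat008       doc008         0.004531  yes
   4  pat009       doc009         0.004531  yes
   5  pat005       doc005         0.005194  yes
   6  pat001       doc001         0.145103  no
   7  pat003       doc003         0.148107  no
   8  pat004       doc004         0.148704  no
   9  pat010       doc010         0.184994  no
  10  pat007       doc007         0.193955  no
  11  pat006       doc006         0.201746  no
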