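index document: doc001
rank  patient      document       distance  relevant
   1  pat010       doc010         0.004352  yes
   2  pat004       doc004         0.007592  yes
   3  pat007       doc007         0.008418  yes
   4  pat006       doc006         0.009417  yes
   5  pat003       doc003         0.009974  yes
   6  pat009       doc009         0.178842  no
   7  pat000       doc000         0.187828  no
   8  pat002       doc002         0.190621  no
   9  pat008       doc008         0.192471  no
  10  pat005       doc005         0.195364  no
  11  pat011       doc011         0.224591  no
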