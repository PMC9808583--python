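,doc000,doc001,doc002,doc003,doc004,doc005,doc006,doc007,doc008,doc009,doc010,doc011
doc000,0.000000000,0.166465515,0.001936203,0.175827599,0.174123275,0.005508133,0.174871066,0.178160497,0.003633644,0.003013772,0.181488839,0.001413081
doc001,0.166465515,0.000000000,0.160652443,0.006655605,0.004909664,0.165476893,0.007071350,0.005873200,0.165415931,0.158601591,0.003501389,0.173793793
doc002,0.001936203,0.160652443,0.000000000,0.170085555,0.168805160,0.007491638,0.168039533,0.170911115,0.003613311,0.003200063,0.173928072,0.001838450
doc003,0.175827599,0.006655605,0.170085555,0.000000000,0.002040150,0.177099935,0.002018305,0.003898574,0.177621514,0.170338210,0.003546688,0.181247737
doc004,0.174123275,0.004909664,0.168805160,0.002040150,0.000000000,0.174058986,0.003444391,0.004463810,0.173986423,0.165194417,0.003923541,0.180604298
doc005,0.005508133,0.165476893,0.007491638,0.177099935,0.174058986,0.000000000,0.173164283,0.175305941,0.006863043,0.006755658,0.178909506,0.006570149
doc006,0.174871066,0.007071350,0.168039533,0.002018305,0.003444391,0.173164283,0.000000000,0.001833622,0.170397437,0.165611513,0.003946082,0.181646647
doc007,0.178160497,0.005873200,0.170911115,0.003898574,0.004463810,0.175305941,0.001833622,0.000000000,0.171286408,0.166065400,0.004500792,0.185152102
doc008,0.003633644,0.165415931,0.003613311,0.177621514,0.173986423,0.006863043,0.170397437,0.171286408,0.000000000,0.000723185,0.179087440,0.003344297
doc009,0.003013772,0.158601591,0.003200063,0.170338210,0.165194417,0.006755658,0.165611513,0.166065400,0.000723185,0.000000000,0.174573278,0.002476475
doc010,0.181488839,0.003501389,0.173928072,0.003546688,0.003923541,0.178909506,0.003946082,0.004500792,0.179087440,0.174573278,0.000000000,0.187835136
doc011,0.001413081,0.173793793,0.001838450,0.181247737,0.180604298,0.006570149,0.181646647,0.185152102,0.003344297,0.002476475,0.187835136,0.000000000
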