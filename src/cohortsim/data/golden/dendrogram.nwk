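(((doc001:0.003501389,doc010:0.003501389):0.003867230,((doc006:0.001833622,doc007:0.001833622):0.002832076,(doc003:0.002040150,doc004:0.002040150):0.002625548):0.002702921):0.417116430,(doc005:0.008323893,((doc008:0.000723185,doc009:0.000723185):0.004011016,(doc002:0.002021614,(doc000:0.001413081,doc011:0.001413081):0.000608532):0.002712587):0.003589692):0.416161156);
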