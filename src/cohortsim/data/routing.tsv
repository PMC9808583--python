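osteoporosis	musculoskeletal,nutritional
nephritis_sle	urogenital,immune
ild_ssc	respiratory,immune
lung_infection	respiratory,infections
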