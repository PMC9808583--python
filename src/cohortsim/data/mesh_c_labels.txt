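# 22 MeSH category-C head chapters used as organ-system labels
# (mental-health chapters deliberately excluded).
infections
neoplasms
musculoskeletal
digestive
stomatognathic
respiratory
otorhinolaryngologic
nervous
ophthalmologic
urogenital
cardiovascular
hemic
congenital
skin
nutritional
endocrine
immune
environmental
animal
pathological
chemically_induced
wounds
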