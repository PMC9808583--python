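pas de	negation
pas d'	negation
sans	negation
aucun	negation
aucune	negation
absence de	negation
absence d'	negation
no	negation
suspicion de	hypothesis
suspicion d'	hypothesis
doute sur	hypothesis
evocateur de	hypothesis
possible	hypothesis
suspicion of	hypothesis
suspected	hypothesis
antecedents familiaux de	family
histoire familiale de	family
chez sa mere	family
chez son pere	family
family history of	family
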