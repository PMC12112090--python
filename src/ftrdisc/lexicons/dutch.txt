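# Dutch closed-vocabulary lexicon for FTR coding.
# Inflection sets are distinct entries (zal/zult/zullen; ga/gaat/gaan).
# "staan op het punt" ('about to') variants are multiword entries.

[future]
zal
zult
zullen
ga
gaat
gaan
sta op het punt
staat op het punt
staan op het punt

[modal]
kan
kunt
kunnen
zou
zouden
misschien
mogelijk
waarschijnlijk
zeker

[contractions]
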