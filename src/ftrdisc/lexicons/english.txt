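# English closed-vocabulary lexicon for FTR coding.
# Future auxiliaries mark the future-tense class; any modal marker
# (high- or low-certainty) suppresses both classes. Multiword entries
# match as contiguous token sequences; "going to" matches after any
# form of "be" ("is/are/am going to") as well as after "gonna" expansion.

[future]
will
shall
going to
about to

[modal]
can
could
may
might
should
would
possibly
probably
perhaps
maybe
definitely
certainly
likely

[contractions]
won't => will not
shan't => shall not
'll => will
gonna => going to
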