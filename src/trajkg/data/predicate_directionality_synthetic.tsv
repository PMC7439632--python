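# Expert directionality assessment of the 47 protein-protein predicates.
# The 12 undirected predicates follow the published assessment; the directed
# list is a SYNTHETIC reconstruction in the same vocabulary style ("inhibits"
# and "catalysis precedes" are attested, the remaining directed predicates are
# plausible stand-ins), preserving the 35 directed / 12 undirected split.
# predicate<TAB>category
binds with	undirected
coexists with	undirected
does not coexist with	undirected
forms protein complex with	undirected
interacts with	undirected
does not interact with	undirected
is associated with	undirected
is compared with	undirected
is functionally related to	undirected
is spatially related to	undirected
is the same as	undirected
ortholog is associated with	undirected
inhibits	directed
catalysis precedes	directed
activates	directed
stimulates	directed
converts to	directed
regulates	directed
positively regulates	directed
negatively regulates	directed
phosphorylates	directed
dephosphorylates	directed
ubiquitinates	directed
methylates	directed
acetylates	directed
glycosylates	directed
cleaves	directed
degrades	directed
transports	directed
controls transport of	directed
controls expression of	directed
controls phosphorylation of	directed
controls state change of	directed
causes	directed
affects	directed
disrupts	directed
augments	directed
produces	directed
precedes	directed
represses	directed
induces	directed
catalyzes conversion of	directed
is upstream of	directed
signals to	directed
activates expression of	directed
inactivates	directed
modifies	directed
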