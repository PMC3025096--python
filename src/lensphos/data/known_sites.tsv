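# Synthetic known-site list: the complement of the novel sites in the packaged
# differential catalog, standing in for a phosphosite-database snapshot.
accession	designation
P43320	Thr-91
P02511	Ser-19
P02511	Ser-76
Q53FA7	Ser-260
P32119	Ser-112
P40925	Ser-241
P04406	Thr-184
P04792	Ser-82
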