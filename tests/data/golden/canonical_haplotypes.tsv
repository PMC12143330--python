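gene_id	animal	flip	comparable
g1	A1	True	True
g1	A2	False	True
g2	A1	True	True
g2	A2	False	True
g3	A1	True	True
g3	A2	False	True
g4	A1	True	True
g4	A2	False	True
g5	A1	False	False
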