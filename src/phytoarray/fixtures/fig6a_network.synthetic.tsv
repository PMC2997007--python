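# Synthetic stand-in network: Rad23A as sole common denominator upstream of
# genes down-regulated >=3-fold by shikonin at 0.5 h.  Constructed topology
# (Rad23A-mediated p300 inactivation plus proteasomal NF-kB branch), not a
# transcription of any published figure.
Rad23A	inhibit	p300
p300	activate	STAT1
p300	activate	IL1B
p300	activate	IL4
p300	activate	NFATC3
p300	activate	PTGS2
Rad23A	activate	26S-proteasome
26S-proteasome	inhibit	NF-kB
NF-kB	activate	TNF
NF-kB	activate	CCL4
NF-kB	activate	CCL8
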