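# Synthetic stand-in network: E6-AP (ubiquitin-protein ligase E3A) as sole
# common denominator upstream of genes down-regulated >=3-fold by emodin at
# 0.5 h; consistent with a blocked (inactive) E6-AP state.  Constructed
# topology, not a transcription of any published figure.
E6-AP	activate	Ub
Ub	activate	NFATC3
Ub	activate	PTGS2
Ub	activate	LILRB4
Ub	activate	TAP2
E6-AP	inhibit	p53
p53	inhibit	ETS1
p53	inhibit	STAT1
p53	inhibit	IL1B
p53	inhibit	IL4
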