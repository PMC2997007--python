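# Synthetic stand-in network: E6-AP as sole common denominator upstream of
# genes down-regulated >=3-fold by BF/S+L/Ep at 12 h, via increased
# ubiquitination of Rad23A and subsequent p300 inactivation.  Constructed
# topology, not a transcription of any published figure.
E6-AP	activate	Ub
Ub	activate	Rad23A
Rad23A	inhibit	p300
p300	activate	IL4
p300	activate	IRF1
p300	activate	GATA3
p300	activate	NFATC3
E6-AP	inhibit	beta-catenin
beta-catenin	activate	CCR2
beta-catenin	activate	CXCR4
beta-catenin	activate	BCL2
beta-catenin	activate	PTGS2
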