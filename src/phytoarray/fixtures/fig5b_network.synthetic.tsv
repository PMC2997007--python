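# Synthetic stand-in signaling network: ERK1/2 as sole common denominator
# reaching the 16 genes up-regulated >=3-fold by cytopiloyne or BF/S+L/Ep at
# 4 h, within <=4 hierarchical regulation levels.  Constructed topology
# (canonical ERK effector branches), not a transcription of any published figure.
ERK1/2	activate	Elk-1
Elk-1	activate	c-Fos
c-Fos	activate	AP-1
AP-1	activate	CSF1
AP-1	activate	IL5
AP-1	activate	TNFSF14
AP-1	activate	MADCAM1
ERK1/2	activate	STAT3
STAT3	activate	CD14
STAT3	activate	TLR3
STAT3	activate	IL1R2
STAT3	activate	TNFRSF10D
ERK1/2	activate	RSK1
RSK1	activate	NF-kB
NF-kB	activate	CCR1
NF-kB	activate	CCR8
NF-kB	activate	ITGAX
NF-kB	activate	CXCR4
NF-kB	activate	TBX21
ERK1/2	activate	MNK1
MNK1	activate	MAP2K4
MNK1	activate	SHC1
MNK1	activate	ADAMDEC1
MEK1/2	activate	ERK1/2
Raf-1	activate	MEK1/2
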