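# Synthetic stand-in network: Lck as sole common denominator upstream of the
# "delayed down-regulation" gene group distinguishing cytopiloyne from
# BF/S+L/Ep, within <=4 regulation levels.  Constructed topology (canonical
# Lck/ZAP-70 and PI3K branches), not a transcription of any published figure.
Lck	activate	ZAP-70
ZAP-70	activate	LAT
LAT	activate	PLC-gamma1
PLC-gamma1	activate	CCL2
PLC-gamma1	activate	IGSF6
Lck	activate	PI3K
PI3K	activate	Akt
Akt	activate	CDH12
Akt	activate	SLAMF1
Akt	activate	CLEC1A
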