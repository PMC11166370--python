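protein_id	he	hl	el
A2M	up	ns	down
CKM	up	ns	down
FLNA	up	ns	down
ITGA2B	up	ns	down
ORM2	up	ns	down
PLTP	up	ns	down
HP	up	ns	ns
QSOX1	up	ns	ns
TGM2	up	ns	ns
FLNC	up	up	ns
HSP70	up	up	ns
MAN2B1	up	up	ns
PF4	ns	ns	ns
TLN1	ns	ns	ns
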