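# Gene-name synonym table: alias (case-insensitive, spaces stripped) -> canonical name.
# Canonical vocabulary: 13 PCGs (atp6 atp8 cox1-3 cytb nad1-6 nad4L), rrnS/rrnL,
# 22 tRNAs trnX with Leu/Ser disambiguation (trnL1=Leu CUN, trnL2=Leu UUR,
# trnS1=Ser AGN, trnS2=Ser UCN), and the DUI ORFans F-orf/M-orf/H-orf.
cox1	cox1
coi	cox1
co1	cox1
cox2	cox2
coii	cox2
co2	cox2
cox3	cox3
coiii	cox3
co3	cox3
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunitiii	cox3
cytb	cytb
cob	cytb
cytochromeb	cytb
atp6	atp6
atpase6	atp6
atp8	atp8
atpase8	atp8
nad1	nad1
nd1	nad1
nad2	nad2
nd2	nad2
nad3	nad3
nd3	nad3
nad4	nad4
nd4	nad4
nad4l	nad4L
nd4l	nad4L
nad5	nad5
nd5	nad5
nad6	nad6
nd6	nad6
rrns	rrnS
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
srrna	rrnS
s-rrna	rrnS
rrn12	rrnS
rrnl	rrnL
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
lrrna	rrnL
l-rrna	rrnL
rrn16	rrnL
forf	F-orf
f-orf	F-orf
morf	M-orf
m-orf	M-orf
horf	H-orf
h-orf	H-orf
trna	trnA
trna-ala	trnA
trnc	trnC
trna-cys	trnC
trnd	trnD
trna-asp	trnD
trne	trnE
trna-glu	trnE
trnf	trnF
trna-phe	trnF
trng	trnG
trna-gly	trnG
trnh	trnH
trna-his	trnH
trni	trnI
trna-ile	trnI
trnk	trnK
trna-lys	trnK
trnl1	trnL1
trna-leu(cun)	trnL1
trnl(cun)	trnL1
trnl2	trnL2
trna-leu(uur)	trnL2
trnl(uur)	trnL2
trnm	trnM
trna-met	trnM
trnn	trnN
trna-asn	trnN
trnp	trnP
trna-pro	trnP
trnq	trnQ
trna-gln	trnQ
trnr	trnR
trna-arg	trnR
trns1	trnS1
trna-ser(agn)	trnS1
trns(agn)	trnS1
trns2	trnS2
trna-ser(ucn)	trnS2
trns(ucn)	trnS2
trnt	trnT
trna-thr	trnT
trnv	trnV
trna-val	trnV
trnw	trnW
trna-trp	trnW
trny	trnY
trna-tyr	trnY
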