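# Default gene-name synonym table: raw annotation label -> canonical symbol.
# Covers tRNA naming variants (anticodon suffixes, elongator/initiator Met),
# ycf numbering/case variants, and identity entries for mixed-case plastid
# gene symbols so they survive normalisation unchanged.
trnM(cau)	trnMe
trnMe(cau)	trnMe
trnM-CAU	trnMe
tRNA-Met	trnMe
trnfM(cau)	trnfM
trnfM-CAU	trnfM
tRNA-fMet	trnfM
trnI(gau)	trnI
trnA(ugc)	trnA
trnL(uaa)	trnL-uaa
trnL(uag)	trnL-uag
trnL(caa)	trnL-caa
trnS(gcu)	trnS-gcu
trnS(uga)	trnS-uga
trnS(gga)	trnS-gga
trnG(gcc)	trnG-gcc
trnG(ucc)	trnG-ucc
trnR(acg)	trnR-acg
trnR(ucu)	trnR-ucu
trnR(ccg)	trnR-ccg
trnV(uac)	trnV
trnF(gaa)	trnF
trnD(guc)	trnD
trnE(uuc)	trnE
trnH(gug)	trnH
trnK(uuu)	trnK
trnN(guu)	trnN
trnP(ugg)	trnP
trnQ(uug)	trnQ
trnT(ugu)	trnT
trnW(cca)	trnW
trnY(gua)	trnY
trnC(gca)	trnC
Ycf1	ycf1
YCF1	ycf1
rbcL	rbcL
rbcS	rbcS
rbcR	rbcR
cbbX	cbbX
rpoA	rpoA
rpoB	rpoB
rpoC1	rpoC1
rpoC2	rpoC2
psaA	psaA
psaB	psaB
psbA	psbA
psbB	psbB
psbC	psbC
psbD	psbD
atpA	atpA
atpB	atpB
atpE	atpE
atpF	atpF
atpH	atpH
atpI	atpI
petA	petA
petB	petB
petD	petD
cemA	cemA
clpC	clpC
apcA	apcA
apcB	apcB
cpeA	cpeA
cpeB	cpeB
chlB	chlB
chlL	chlL
chlN	chlN
chlI	chlI
leuC	leuC
leuD	leuD
menA	menA
menB	menB
menC	menC
menD	menD
menE	menE
menF	menF
cox1	cox1
16S ribosomal RNA	rrs
16S rRNA	rrs
rrn16	rrs
23S ribosomal RNA	rrl
23S rRNA	rrl
rrn23	rrl
5S ribosomal RNA	rrf
5S rRNA	rrf
rrn5	rrf
rnpB	rnpB
ssrA	ssrA
ffs	ffs
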