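pathway	ligand	receptor	cofactor
CALC	Calcb	Calcrl
SST	Sst	Sstr1
VIP	Vip	Vipr1
VIP	Vip	Vipr2
NRTN	Nrtn	Gfra2
FGF	Fgf1	Fgfr2
FGF	Fgf1	Fgfr3
EDN	Edn1	Ednrb
NMU	Nmu	Nmur1
TAC	Tac1	Tacr1
BMP	Bmp4	Bmpr1a;Bmpr2
NRG	Nrg1	Erbb2;Erbb3
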