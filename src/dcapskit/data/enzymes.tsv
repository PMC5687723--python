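# dcapskit restriction enzyme catalogue
# dialect: name<TAB>site-with-^-top-cut<TAB>[bottom-cut | top/bottom | nick | double]
AatII	GACGT^C
Acc65I	G^GTACC
AccI	GT^MKAC
AciI	C^CGC
AclI	AA^CGTT
AcuI	CTGAAG	22/20
AfeI	AGC^GCT
AflII	C^TTAAG
AflIII	A^CRYGT
AgeI	A^CCGGT
AhdI	GACNNN^NNGTC
AleI	CACNN^NNGTG
AluI	AG^CT
AlwI	GGATC	9/10
AlwNI	CAGNNN^CTG
ApaI	GGGCC^C
ApaLI	G^TGCAC
ApeKI	G^CWGC
ApoI	R^AATTY
AscI	GG^CGCGCC
AseI	AT^TAAT
AsiSI	GCGAT^CGC
AvaI	C^YCGRG
AvaII	G^GWCC
AvrII	C^CTAGG
BaeGI	GKGCM^C
BamHI	G^GATCC
BanI	G^GYRCC
BanII	GRGCY^C
BbsI	GAAGAC	8/12
BbvCI	CC^TCAGC
BbvI	GCAGC	13/17
BccI	CCATC	9/10
BceAI	ACGGC	17/19
BcgI	CGANNNNNNTGC	double
BciVI	GTATCC	12/11
BclI	T^GATCA
BcoDI	GTCTC	6/10
BfaI	C^TAG
BfuAI	ACCTGC	10/14
BglI	GCCNNNN^NGGC
BglII	A^GATCT
BlpI	GC^TNAGC
BmgBI	CAC^GTC
BmrI	ACTGGG	11/10
BmtI	GCTAG^C
BpmI	CTGGAG	22/20
Bpu10I	CC^TNAGC
BpuEI	CTTGAG	22/20
BsaAI	YAC^GTR
BsaBI	GATNN^NNATC
BsaHI	GR^CGYC
BsaI	GGTCTC	7/11
BsaJI	C^CNNGG
BsaWI	W^CCGGW
BseRI	GAGGAG	16/14
BseYI	C^CCAGC
BsgI	GTGCAG	22/20
BsiEI	CGRY^CG
BsiHKAI	GWGCW^C
BsiWI	C^GTACG
BslI	CCNNNNN^NNGG
BsmAI	GTCTC	6/10
BsmBI	CGTCTC	7/11
BsmFI	GGGAC	15/19
BsmI	GAATGC	7/5
BsoBI	C^YCGRG
Bsp1286I	GDGCH^C
BspCNI	CTCAG	14/12
BspDI	AT^CGAT
BspEI	T^CCGGA
BspHI	T^CATGA
BspMI	ACCTGC	10/14
BspQI	GCTCTTC	8/11
BsrBI	CCG^CTC
BsrDI	GCAATG	8/6
BsrFI	R^CCGGY
BsrGI	T^GTACA
BsrI	ACTGG	6/4
BssHII	G^CGCGC
BssSI	C^ACGAG
BstAPI	GCANNNN^NTGC
BstBI	TT^CGAA
BstEII	G^GTNACC
BstNI	CC^WGG
BstUI	CG^CG
BstXI	CCANNNNN^NTGG
BstYI	R^GATCY
BstZ17I	GTA^TAC
Bsu36I	CC^TNAGG
BtgI	C^CRYGG
BtgZI	GCGATG	16/20
BtsCI	GGATG	7/5
BtsI	GCAGTG	8/6
BtsIMutI	CAGTG	7/5
Cac8I	GCN^NGC
ClaI	AT^CGAT
CviAII	C^ATG
CviKI_1	RG^CY
CviQI	G^TAC
DdeI	C^TNAG
DpnI	GA^TC
DpnII	^GATC
DraI	TTT^AAA
DraIII	CACNNN^GTG
DrdI	GACNNNN^NNGTC
EaeI	Y^GGCCR
EagI	C^GGCCG
EarI	CTCTTC	7/10
EciI	GGCGGA	17/15
Eco53kI	GAG^CTC
EcoNI	CCTNN^NNNAGG
EcoO109I	RG^GNCCY
EcoRI	G^AATTC
EcoRV	GAT^ATC
Esp3I	CGTCTC	7/11
FatI	^CATG
FauI	CCCGC	9/11
Fnu4HI	GC^NGC
FokI	GGATG	14/18
FseI	GGCCGG^CC
FspI	TGC^GCA
HaeII	RGCGC^Y
HaeIII	GG^CC
HgaI	GACGC	10/15
HhaI	GCG^C
HinP1I	G^CGC
HincII	GTY^RAC
HindIII	A^AGCTT
HinfI	G^ANTC
HpaI	GTT^AAC
HpaII	C^CGG
HphI	GGTGA	13/12
Hpy166II	GTN^NAC
Hpy188I	TCN^GA
Hpy188III	TC^NNGA
Hpy99I	CGWCG^
HpyAV	CCTTC	11/10
HpyCH4III	ACN^GT
HpyCH4IV	A^CGT
HpyCH4V	TG^CA
KasI	G^GCGCC
KpnI	GGTAC^C
LpnPI	CCDG	14/18
MboI	^GATC
MboII	GAAGA	13/12
MfeI	C^AATTG
MluCI	^AATT
MluI	A^CGCGT
MlyI	GAGTC	10/10
MmeI	TCCRAC	26/24
MnlI	CCTC	11/10
MscI	TGG^CCA
MseI	T^TAA
MslI	CAYNN^NNRTG
MspA1I	CMG^CKG
MspI	C^CGG
MspJI	CNNR	13/17
MwoI	GCNNNNN^NNGC
NaeI	GCC^GGC
NarI	GG^CGCC
NciI	CC^SGG
NcoI	C^CATGG
NdeI	CA^TATG
NgoMIV	G^CCGGC
NheI	G^CTAGC
NlaIII	CATG^
NlaIV	GGN^NCC
NmeAIII	GCCGAG	27/25
NotI	GC^GGCCGC
NruI	TCG^CGA
NsiI	ATGCA^T
NspI	RCATG^Y
Nt.BspQI	GCTCTTC	nick
PacI	TTAAT^TAA
PaeR7I	C^TCGAG
PaqCI	CACCTGC	11/15
PciI	A^CATGT
PflFI	GACN^NNGTC
PflMI	CCANNNN^NTGG
PleI	GAGTC	9/10
PluTI	GGCGC^C
PmeI	GTTT^AAAC
PmlI	CAC^GTG
PpuMI	RG^GWCCY
PshAI	GACNN^NNGTC
PsiI	TTA^TAA
PspGI	^CCWGG
PspOMI	G^GGCCC
PspXI	VC^TCGAGB
PstI	CTGCA^G
PvuI	CGAT^CG
PvuII	CAG^CTG
RsaI	GT^AC
RsrII	CG^GWCCG
SacI	GAGCT^C
SacII	CCGC^GG
SalI	G^TCGAC
SapI	GCTCTTC	8/11
Sau3AI	^GATC
Sau96I	G^GNCC
SbfI	CCTGCA^GG
ScaI	AGT^ACT
ScrFI	CC^NGG
SexAI	A^CCWGGT
SfaNI	GCATC	10/14
SfcI	C^TRYAG
SfiI	GGCCNNNN^NGGCC
SfoI	GGC^GCC
SgrAI	CR^CCGGYG
SmaI	CCC^GGG
SmlI	C^TYRAG
SnaBI	TAC^GTA
SpeI	A^CTAGT
SphI	GCATG^C
SrfI	GCCC^GGGC
SspI	AAT^ATT
StuI	AGG^CCT
StyD4I	^CCNGG
StyI	C^CWWGG
SwaI	ATTT^AAAT
TaqI	T^CGA
TfiI	G^AWTC
TseI	G^CWGC
Tsp45I	^GTSAC
TspMI	C^CCGGG
TspRI	CASTG	7/-2
Tth111I	GACN^NNGTC
XbaI	T^CTAGA
XcmI	CCANNNNN^NNNNTGG
XhoI	C^TCGAG
XmaI	C^CCGGG
XmnI	GAANN^NNTTC
ZraI	GAC^GTC
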