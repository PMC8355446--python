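gene	inheritance	rsids	classifications	nearest	w19kb	w94kb	w138kb	w258kb
CCND2	Dominant	rs76895963	Fetal and Maternal_-_Same Direction	1	1	1	1	1
JAG1	Dominant	rs6040076	Unclassified	1	1	1	1	1
PIK3R1	Dominant/recessive	rs28365970	Unclassified	1	1	1	1	1
PTCH1	Dominant/recessive	rs28457693	Fetal Only	1	1	1	1	1
PTH1R	Dominant	rs2168443	Fetal and Maternal_-_Same Direction	1	1	1	1	1
RIT1	Dominant	rs670523	Unclassified	1	1	1	1	1
RORA	Dominant	rs339969	Fetal and Maternal_-_Same Direction	1	1	1	1	1
SPRED1	Dominant	rs75844534	Fetal and Maternal_-_Opposite Directions	1	1	1	1	1
STAT1	Dominant/recessive	rs2280235	Unclassified	1	1	1	1	1
WT1	Dominant	rs5030317	Unclassified	1	1	1	1	1
IGF2	Dominant	rs11042596	Fetal Only	1		1	1	1
PDE10A	Dominant	rs2934844	Unclassified	1		1	1	1
MAFB	Dominant	rs1012167	Fetal Only	1				1
IGF1R	Dominant/recessive	rs11630479;rs7402983	Unclassified;Fetal Only	2	2	2	2	2
NR2F2	Dominant	rs55958435;rs138715366	Unclassified		1	1	1	1
CAMK2B	Dominant	rs2908279	Fetal Only;Unclassified		1	2	2	2
CDKN1C	Dominant	rs234864	Fetal Only			1	1	1
CNOT3	Dominant	rs255773	Unclassified			1	1	1
DLG4	Dominant	rs222857	Fetal Only			1	1	1
EDNRB	Dominant	rs9318511	Unclassified			1	1	1
FGFR1	Dominant	rs34036147	Fetal Only			1	1	1
HIST1H1E	Dominant	rs9379832	Unclassified			1	1	1
HIST1H4C	Dominant	rs9379832	Unclassified			1	1	1
KIF11	Dominant	rs1112718	Fetal and Maternal_-_Opposite Directions			1	1	1
SLC2A1	Dominant	rs12401656	Fetal Only			1	1	1
P4HB	Dominant	rs9912553;rs73354194	Unclassified;Fetal Only			1	1	2
GJC2	Dominant/recessive	rs708122	Unclassified				1	1
SETD2	Dominant	rs2168443	Fetal and Maternal_-_Same Direction				1	1
ACVR1	Dominant	rs56188432	Fetal Only					1
CHD3	Dominant	rs78378222	Unclassified					1
GNAS	Dominant	rs6026449	Fetal Only					1
KAT6A	Dominant	rs13266210	Fetal Only					1
NF1	Dominant	rs7223535	Unclassified					1
NOTCH1	Dominant	rs28505901	Fetal Only					1
PHF21A	Dominant	rs10437653	Unclassified					1
PITX3	Dominant	rs562974282	Fetal and Maternal_-_Opposite Directions					1
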