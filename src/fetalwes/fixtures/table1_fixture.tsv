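# The 52 diagnostic findings of the 610-fetus prenatal exome cohort,
# one row per diagnosed fetus, as agreed by the clinical review panel.
diagnosis_id	phenotype_class	gene	consequence	inheritance	zygosity
PP0087	skeletal	DYNC2H1	Two stop gained mutations	Inherited	Compound heterozygous
PP0174	multisystem	NRAS	Missense variant	De novo	Heterozygous
PP0184	cardiac	NR2F2	Missense variant	De novo	Heterozygous
PP0204	skeletal	ZC4H2	Frameshift variant	De novo	Heterozygous
PP0258	abdominal	MYCN	Missense variant	Inherited from affected parent	Heterozygous
PP0318	skeletal	CHRNG	Frameshift variant	Inherited	Homozygous
PP0333	cardiac	GATA4	Frameshift variant	De novo (presumed)	Heterozygous
PP0342	multisystem	CHRNG	Frameshift variant	Inherited	Compound heterozygous
PP0384	brain	B3GLCT	Splice donor variant	Inherited	Homozygous
PP0390	cardiac	CCDC103	Missense variant	Inherited	Homozygous
PP0513	cardiac	DNAH11	Stop gained	Inherited	Homozygous
PP0555	multisystem	EVC2	Frameshift variant	Inherited	Homozygous
PP0602	increased_NT	NA	Uniparental disomy on chromosome 15	Uniparental disomy	NA
PP0656	multisystem	PKD1/TSC2	41.2kb deletion	De novo (copy number variation)	Heterozygous
PP0659	multisystem	RAPSN	Splice donor variant	Inherited	Homozygous
PP0792	skeletal	COL1A1	Missense variant	De novo	Heterozygous
PP0981	multisystem	GBA	Frameshift variant	Inherited	Homozygous
PP1408	multisystem	SOX9	Missense variant	De novo	Heterozygous
PP1462	multisystem	BRAF	Missense variant	De novo	Heterozygous
PP1561	skeletal	PIK3CA	Missense variant	De novo	Heterozygous
PP1573	hydrops	KMT2D	Frameshift variant	De novo	Heterozygous
PP1579	brain	TUBB	Missense variant	De novo	Heterozygous
PP1627	multisystem	PIEZO1	Three missense variants	Inherited	Compound heterozygous
PP1711	facial_cleft	SF3B4	Frameshift variant	De novo	Heterozygous
PP1726	cardiac	TAB2	Frameshift variant	De novo	Heterozygous
PP1750	cardiac	ANKRD11	Frameshift variant	De novo	Heterozygous
PP1753	multisystem	CDKN1C	Frameshift variant	Inherited	Heterozygous
PP1780	multisystem	TCTN2	Splice acceptor	Inherited	Homozygous
PP1795	multisystem	COQ9	Stop gained	Inherited	Homozygous
PP1807	increased_NT	MID1	Stop gained	De novo	Hemizygous
PP1843	multisystem	KMT2D	Stop gained	De novo	Heterozygous
PP1864	cardiac	KMT2D	Splice donor variant	De novo	Heterozygous
PP1892	cardiac	SOS1	Protein altering variant	De novo	Heterozygous
PP1934	skeletal	COL1A1	Missense variant	De novo	Heterozygous
PP1967	multisystem	PTPN11	Missense variant	De novo	Heterozygous
PP2000	multisystem	RYR1	Stop gained and frameshift variant	Inherited	Compound heterozygous
PP2009	skeletal	ARCN1	Frameshift variant	De novo	Heterozygous
PP2015	multisystem	FLNB	Missense variant	De novo	Heterozygous
PP2033	cardiac	CHD7	Frameshift variant	De novo	Heterozygous
PP2039	hydrops	NIPBL	Stop gained	De novo	Heterozygous
PP2141	skeletal	FGFR3	Missense variant	De novo	Heterozygous
PP2645	multisystem	TFAP2A	Missense variant	De novo	Heterozygous
PP2718	multisystem	CHD7	Stop gained	De novo	Heterozygous
PP2904	spinal	EPHB4	Frameshift variant	De novo	Heterozygous
PP2979	multisystem	CHD7	Frameshift variant	De novo	Heterozygous
PP3168	multisystem	RIT1	Missense variant	De novo	Heterozygous
PP3246	skeletal	NALCN	Missense variant	De novo (presumed)	Heterozygous
PP3387	multisystem	RAB23	Stop gained	Inherited	Homozygous
PP3540	skeletal	FGFR3	Missense variant	De novo	Heterozygous
PP0626	multisystem	RIT1	Missense variant	Inherited	Heterozygous
PP2567	hydrops	PTPN11	Missense variant	Inherited	Heterozygous
PP0503	increased_NT	PTPN11	Missense variant	Inherited	Heterozygous
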