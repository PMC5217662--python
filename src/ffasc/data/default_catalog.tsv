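# FFASC default orthologous-group catalog.
# 49 OGs relevant for free-fatty-acid (FFA) production in cyanobacteria,
# grouped as rOG (required), pOG (positive impact) and nOG (negative impact),
# with the engineering action each criterion encodes.
# Columns: og_id, category, action_label, member_protein_id, domain_accessions
# (semicolon-separated Pfam accessions; empty = no domain requirement, hits
# from that member bypass the domain-completeness filter).
# The split of the 64 member proteins across OGs beyond one representative
# gene per OG is a synthetic reconstruction: the original per-OG membership
# and the per-member Pfam requirements come from a curation that is not
# redistributed here, so domain_accessions are left empty for users to fill.
og_id	category	action_label	member_protein_id	domain_accessions
K00873	rOG	present	pykf
K00873	rOG	present	pyk_syn
K01007	rOG	present	pps
K00161	rOG	present	pdhA
K00162	rOG	present	pdhB
K00627	rOG	present	odhB
K00382	rOG	present	phdD
K00648	rOG	present	fabH
K00645	rOG	present	fabD
K09458	rOG	present	fabF
K02372	rOG	present	fabZ
K00208	rOG	present	fabI
K01046	rOG	present	lipase
K01046	rOG	present	lipase_sll1969
K01962	pOG	overexpression	accA
K01962	pOG	overexpression	accA_sll0728
K01963	pOG	overexpression	accD
K01963	pOG	overexpression	accD_sll0336
K01961	pOG	overexpression	accC
K01961	pOG	overexpression	accC_sll0053
K02160	pOG	overexpression	accB
K02160	pOG	overexpression	accB_slr0435
K00432	pOG	overexpression	Synpcc7942_1214
K00432	pOG	overexpression	gpx_slr1992
K04564	pOG	overexpression	Synpcc7942_0801
K04564	pOG	overexpression	sod_slr1516
K06198	pOG	overexpression	Synpcc7942_0437
K03782	pOG	overexpression	Synpcc7942_1656
K03782	pOG	overexpression	katG_sll1987
K03621	pOG	overexpression	plsX
K08591	pOG	overexpression	plsY
K00655	pOG	overexpression	plsC
virNOG10454	pOG	overexpression	PDAT1
virNOG19439	pOG	overexpression	oleosins
K14457	pOG	insert	DGTT2
virNOG24576	pOG	overexpression	LCIA
virNOG22763	pOG	overexpression	LCIB
K00006	pOG	overexpression	GPDH
K01601	pOG	insert	rbcL
K01601	pOG	insert	rbcL_slr0009
K01602	pOG	insert	rbcS
K01602	pOG	insert	rbcS_slr0012
K01648	pOG	insert	acl
K10804	pOG	insert	tesA
K10804	pOG	insert	tesA_trunc
K10781	pOG	insert	fatB
K10781	pOG	insert	fatB2
K10782	pOG	insert	fat1
K14075	pOG	insert	gpl
K14075	pOG	insert	plrp2
K01595	nOG	underexpression	ppc
K01897	nOG	knockout	fadD
K01897	nOG	knockout	aas
K00059	nOG	knockout	fabG
K00626	nOG	knockout	thi
K11003	nOG	knockout	hemolysin
cyaNOG01264	nOG	knockout	PBP2
K13788	nOG	knockout	pta
K13282	nOG	knockout	slr2001
K03802	nOG	knockout	slr2002
cyaNOG01069	nOG	knockout	porin
K13535	nOG	underexpression	Thaps3_264297
K00030	nOG	knockout	idh
K03603	nOG	knockout	fadR
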