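enzyme_id	gene	enzyme_name	reference_species	uniprot_id	length_aa	pfam_domain_ids	model_policy	domain_starts
ppk1	ppk1	Polyphosphate kinase	Escherichia coli	E7QTB5	688	PF02503,PF13090,PF17941,PF13089	de_novo_full	
ppk2	ppk2	Polyphosphate kinase 2	Mycobacterium tuberculosis	O05877	295	PF03976	pfam_domains	98
ppx	ppx	Ppx/GppA phosphatase	Escherichia coli	P0AFL6	513	PF02541	pfam_domains	207
glgC	glgC	Glucose-1-phosphate adenylyltransferase	Escherichia coli	P0A6V1	431	PF00483	pfam_domains	166
glgA	glgA	Glycogen synthase	Escherichia coli	P0A6U8	477	PF08323,PF00534	pfam_domains	93,285
glgB_gh57	glgB	Alpha-1,4-glucan branching enzyme (GH57)	Thermococcus kodakaraensis	Q5JDJ7	675	PF09210,PF03065,PF14520	de_novo_full	
glgB_gh13	glgB	Alpha-1,4-glucan branching enzyme (GH13)	Escherichia coli	P07762	728	PF02922,PF00128,PF02806	de_novo_full	
treS	treS	Trehalose synthase/amylase	Mycobacterium tuberculosis	P9WQ19	601	PF00128,PF16657	de_novo_full	
pep2	pep2	Maltokinase	Mycobacterium tuberculosis	Q7DAF6	455	PF18085	de_novo_full	
glgE	glgE	Alpha-1,4-glucan: maltose-1-phosphate maltosyltransferase	Mycobacterium tuberculosis	P9WQ17	701	PF00128,PF11896	de_novo_full	
rv3032	Rv3032	Glycogen synthase (Rv3032)	Mycobacterium tuberculosis	P9WMY9	414	PF13439,PF00534	pfam_domains	72,243
phaA	phaA	Acetyl-CoA acetyltransferase	Cupriavidus necator	P14611	246	PF02803,PF00108	pfam_domains	16,131
phaB	phaB	Acetoacetyl-CoA reductase	Cupriavidus necator	P14697	393	PF00106	pfam_domains	147
phaC_group1	phaC	Poly(3-hydroxyalkanoate) polymerase subunit C (Group 1)	Allochromatium vinosum	P45370	355	PF00561	pfam_domains	128
phaC_group2	phaC	Class II poly(R)-hydroxyalkanoic acid synthase (Group 2)	Pseudomonas aeruginosa	Q51513	559	PF07167	pfam_domains	230
fabG	fabG	3-Oxoacyl-[acyl-carrier-protein] reductase	Escherichia coli	P0AEK2	244	PF13561	pfam_domains	72
phaJ	phaJ	(R)-Enoyl-CoA hydratase/enoyl-CoA hydratase I	Pseudomonas aeruginosa	Q9LBK2	156	PF01575	pfam_domains	28
fabD	fabD	Malonyl CoA-acyl carrier protein transacylase	Escherichia coli	P0AAI9	209	PF00698	pfam_domains	55
sucD	sucD	Succinic semialdehyde dehydrogenase	Clostridium kluyveri	P38947	453	PF00171	pfam_domains	177
4hbD	4hbD	NAD-dependent 4-hydroxybutyrate dehydrogenase	Clostridium kluyveri	P38945	371	PF00465	pfam_domains	136
orfZ	orfZ	4-Hydroxybutyrate CoA-transferase	Clostridium kluyveri	A0A1L5FD42	437	PF02550,PF13336	pfam_domains	79,258
pdat	PDAT	Phospholipid:diacylglycerol acyltransferase	Saccharomyces cerevisiae	P40345	661	PF02450	pfam_domains	281
ws_dgat	wax-dgaT	Wax ester synthase/acyl-CoA:diacylglycerol acyltransferase	Acinetobacter baylyi	Q8GGG1	458	PF06974,PF03007	pfam_domains	86,272
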