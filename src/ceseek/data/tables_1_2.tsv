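gene	domain	phylum	order	n_species	duration_ma	complex	pathway_group
nuoL	Bacteria	Aquificae	Aquificales	6	2075	Complex I	
dxs	Bacteria	Alpha-proteobacteria	Rhodospirillales	5	48	DXS	
psbA	Bacteria	Cyanobacteria	Nostocales, Oscillatoriales	13	2322	PS II	PS II
psbD	Bacteria	Cyanobacteria	Nostocales, Synechococcales, Oscillatoriales, Chroococcales	20	2594	PS II	PS II
ftsH	Bacteria	Deinococcus-Thermus	Deinococcales	5	439	FtsH	
eftA	Bacteria	Beta-proteobacteria	Burkholderiales	10	936	ETF	ETF
eftB	Bacteria	Beta-proteobacteria	Burkholderiales	9	936	ETF	ETF
amoA	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	AMO	ammonia oxidation
amoB	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	AMO	ammonia oxidation
amoC	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	AMO	ammonia oxidation
amoD	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449		ammonia oxidation
amoE	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449		ammonia oxidation
haoA	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	HAO/c554	ammonia oxidation
haoB	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449		ammonia oxidation
cycA	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	HAO/c554	ammonia oxidation
cycB	Bacteria	Beta-proteobacteria	Nitrosomonadales	8	449	Cyt c_m552	ammonia oxidation
fla	Bacteria	Gamma-proteobacteria	Alteromonadales	8	1733	Filament	
tkt	Bacteria	Gamma-proteobacteria	Vibrionales	6	124	TKT	
tuf	Bacteria	6 phyla	29 orders	221	3936		
mtmB	Archaea	Euryarchaeota	Methanosarcinales	7	496	MtmB-MtmC	MtmB-MtmC
mtmC	Archaea	Euryarchaeota	Methanosarcinales	6	496	MtmB-MtmC	MtmB-MtmC
mtbB	Archaea	Euryarchaeota	Methanosarcinales	8	496	MtbB-MtbC	MtbB-MtbC
mtbC	Archaea	Euryarchaeota	Methanosarcinales	6	496	MtbB-MtbC	MtbB-MtbC
mtrA	Archaea	Euryarchaeota	Methanomicrobiales, Methanococcales	12	1943	Mtr	
glnB	Archaea	Euryarchaeota	Methanococcales	5	1943	GlnB	
histone	Archaea	Euryarchaeota	Methanococcales	5	1183	Archaeal histone	
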