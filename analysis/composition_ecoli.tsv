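# Representative exponential-growth E. coli cytosol composition (synthetic
# stand-in table assembled from typical literature concentrations; columns:
# name, concentration in mM, net charge at cytosolic pH, packing radius in Å,
# abundance class).
name	mM	charge	radius_A	class
glutamate	96.0	-1	3.5	auto
glutathione	17.0	-1	4.2	auto
fructose-1,6-bisphosphate	15.0	-4	4.3	auto
atp	9.6	-4	4.8	auto
utp	8.3	-4	4.7	auto
gtp	4.9	-4	4.8	auto
aspartate	4.2	-1	3.3	auto
valine	4.0	0	3.4	auto
glutamine	3.8	0	3.5	auto
6-phosphogluconate	3.8	-3	4.1	auto
citrate	2.0	-3	3.8	auto
nad	2.6	-1	5.0	auto
alanine	2.6	0	3.1	auto
udp-glucose	2.5	-2	4.6	auto
malate	1.7	-2	3.5	auto
coenzyme-a	1.4	-4	5.2	auto
ctp	2.7	-4	4.7	auto
glycerate	1.0	-1	3.2	auto
phosphoenolpyruvate	0.18	-3	3.5	rare
succinate	0.57	-2	3.4	rare
arginine	0.57	1	3.7	rare
3-phosphoglycerate	1.5	-3	3.7	rare
fumarate	0.12	-2	3.4	rare
dihydroxyacetone-phosphate	0.37	-2	3.5	rare
serine	0.068	0	3.1	rare
lysine	0.41	1	3.6	rare
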