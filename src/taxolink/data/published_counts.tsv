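kind	IndexFungorum	IPNI	ION
TotalNames	507279	1721566	5309468
NamesWithPublications	444235	1708187	1729338
DOI	75009	245846	401351
Handle	3	1157	35731
JSTOR	5578	131401	28146
BioStor	322	52395	170250
BHL	6818	107459	5
URL	32064	97396	127041
PDF	12864	34319	231156
WikidataQID	94192	396072	515341
Any	105886	522601	769956
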