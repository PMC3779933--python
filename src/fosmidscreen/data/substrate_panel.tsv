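substrate	enzyme	function	concentration	detection	assay_type
AZCL-HE-Cellulose	Cellulase	Cellulose degradation	0.1% (w/v)	590	liquid
4-MUB-b-D-Cellobiose	Cellobiohydrolase	Cellulose degradation	1 mM	365/450	liquid
PNP-b-D-Glucoside	beta-Glucosidase	Cellulose degradation	1 mM	410	liquid
AZCL-Xylan	Xylanase	Hemicellulose degradation	0.1% (w/v)	590	liquid
4-MUB-b-D-Xyloside	beta-Xylosidase	Hemicellulose degradation	1 mM	365/450	liquid
Starch Azure	alpha-Amylase	Starch degradation	0.5% (w/v)	590	liquid
4-MUB-a-D-Glucoside	alpha-Glucosidase	Starch degradation	1 mM	365/450	liquid
Chitin Azure	Chitinase	Chitin degradation	0.1% (w/v)	590	liquid
4-MUB-b-N-Acetylglucosamine	N-Acetyl-beta-D-glucosaminidase	Chitin degradation	1 mM	365/450	liquid
L-DOPA	Polyphenol oxidase	Lignin degradation	5 mM	480	liquid
Syringaldazine	Laccase	Lignin degradation	40 uM	530	liquid
BCIP	Phosphatase	Phosphate mineralization	0.1 mM	visual	solid
Skim milk	Protease	Protein turnover	2%	visual	solid
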