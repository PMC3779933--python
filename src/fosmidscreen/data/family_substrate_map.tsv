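# Default CAZy-family -> assayable-substrate relation used to turn per-ORF
# annotations into predicted activity profiles. Edit freely: one family per
# line, substrates comma-separated (empty = family predicts nothing, e.g.
# carbohydrate-binding modules, which bind but do not hydrolyse).
family	substrates
GH1	PNP-b-D-Glucoside,4-MUB-b-D-Cellobiose,4-MUB-b-D-Xyloside
GH3	PNP-b-D-Glucoside,4-MUB-b-D-Cellobiose,4-MUB-b-D-Xyloside
GH9	AZCL-HE-Cellulose,4-MUB-b-D-Cellobiose
GH10	AZCL-Xylan,4-MUB-b-D-Cellobiose
GH13	Starch Azure,4-MUB-a-D-Glucoside
GH15	Starch Azure,4-MUB-a-D-Glucoside
GH31	Starch Azure,4-MUB-a-D-Glucoside
GH97	Starch Azure,4-MUB-a-D-Glucoside
GH2	4-MUB-b-N-Acetylglucosamine
GH20	4-MUB-b-N-Acetylglucosamine
GH84	4-MUB-b-N-Acetylglucosamine
GH109	4-MUB-b-N-Acetylglucosamine
phosphatase	BCIP
peptidase	Skim milk
CBM
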