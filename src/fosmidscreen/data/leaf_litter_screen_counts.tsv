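# Published per-library, per-substrate positive-assay counts from a
# seven-library leaf-litter fosmid screening campaign (143,228 clones screened;
# 374 unique positive clones). The n_clones row gives clones screened per
# library. Used as a worked input for tally arithmetic.
# reported_n_clones_screened=143228
# reported_n_unique_clones=374
substrate	Dec10_01XX	Dec10_08XX	Feb11_01XX	Feb11_08XX	Feb11_16XN	Mar12_01XX	Mar12_08XX
n_clones	21755	18540	10830	15105	26818	25080	25080
AZCL-HE-Cellulose	0	1	0	0	4	0	0
4-MUB-b-D-Cellobiose	12	23	13	9	31	6	6
PNP-b-D-Glucoside	6	11	9	6	14	4	1
AZCL-Xylan	5	5	7	6	6	2	1
4-MUB-b-D-Xyloside	24	19	20	11	31	14	8
Starch Azure	2	1	2	0	1	1	0
4-MUB-a-D-Glucoside	4	4	0	2	3	0	0
Chitin Azure	0	0	0	0	0	0	0
4-MUB-b-N-Acetylglucosamine	8	16	7	15	19	2	4
L-DOPA	0	0	0	0	0	0	0
Syringaldazine	0	0	0	0	0	0	0
BCIP	9	10	4	3	7	0	1
Skim milk	0	1	1	0	0	0	2
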