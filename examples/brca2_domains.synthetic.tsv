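name	aa_start	aa_end
PALB2_BD	21	39
BRC_repeats	1002	2085
Helical	2479	2667
OB_fold_1	2670	2799
OB_fold_2	2804	3054
OB_fold_3	3057	3193
DBD	2479	3193
CT_RAD51_BD	3270	3305
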