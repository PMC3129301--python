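# TE/repeat/gene annotation of the 113 605 bp wheat BAC clone 2383A24
# name	category	copies	length_bp
RLG_Egug_2383A24_solo_LTR	class I / LTR / gypsy	1	1503
RLG_Wilma_2383A24_solo_LTR	class I / LTR / gypsy	1	1490
RLG_Sabrina_2383A24-1p	class I / LTR / gypsy	1	1505
RLG_Fatima_2383A24-1p_-2_-3	class I / LTR / gypsy	3	27210
RLC_WIS_2383A24-1	class I / LTR / copia	1	8353
RLC_Barbara_2383A24-1p	class I / LTR / copia	1	6384
RLC_Claudia_2383A24-1p	class I / LTR / copia	1	9579
RLX_Xalax_2383A24-1p	class I / LTR / unknown	1	1566
RIX_2383A24-1p	class I / non-LTR	1	1014
DTC_Caspar_2383A24-1p	class II / CACTA	1	3693
MITEs	MITE	6	747
Spelt1_tandem_repeats	tandem_repeat	6	1010
genes	gene	5	4913
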