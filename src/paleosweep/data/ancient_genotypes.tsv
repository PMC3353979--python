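sample	site	period	c14_bp	genotype	replicates
LaPasiega_1	La Pasiega (Cantabria)	Magdalenian		TT	TT,TT
LaChora_1	La Chora (Cantabria)	Magdalenian		TT	TT,TT
Erralla_1	Erralla (Gipuzkoa)	Magdalenian	12319	TT	TT,TT
Marizulo_1	Marizulo (Gipuzkoa)	Neolithic	5285	TT	TT,TT
SJAPL_01	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_02	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_03	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_04	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_05	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_06	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_07	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_08	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_09	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_10	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_11	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_12	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_13	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_14	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_15	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_16	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
SJAPL_17	SJAPL (Araba)	Late-Neolithic	5070	TT	TT,TT
Longar_1	Longar (Navarre)	Neolithic-Calcolithic	4445	TT	TT,TT
Longar_2	Longar (Navarre)	Neolithic-Calcolithic	4445	TT	TT,TT
Longar_3	Longar (Navarre)	Neolithic-Calcolithic	4445	TT	TT,TT
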