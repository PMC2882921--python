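gene,family,role,probe_sets,receptor_of,also_family
IGF1R,OTHER,RECEPTOR,203627_at,IGF1,
MET,OTHER,RECEPTOR,203510_at,HGF,
CCR1,OTHER,RECEPTOR,205098_at,CCL3,
PTPRZ1,OTHER,RECEPTOR,204469_at,PTN,
NTRK2,OTHER,RECEPTOR,207152_at,BDNF,
IL6R,IL6_FAMILY,RECEPTOR,205945_at,IL6,
IL6ST,IL6_FAMILY,RECEPTOR,212195_at,IL6,
CNTFR,IL6_FAMILY,RECEPTOR,,CNTF,
OSMR,IL6_FAMILY,RECEPTOR,205729_at,OSM,
LIFR,IL6_FAMILY,RECEPTOR,225575_at,LIF,
IL11RA,IL6_FAMILY,RECEPTOR,204773_at,IL11,
CRLF1,IL6_FAMILY,RECEPTOR,206315_at,CLCF1,
IL1R1,OTHER,RECEPTOR,202948_at,IL1B,
IL10RA,OTHER,RECEPTOR,204912_at,IL10,
IL10RB,OTHER,RECEPTOR,209575_at,IL10,
IL15RA,OTHER,RECEPTOR,207375_s_at,IL15,
IL21R,OTHER,RECEPTOR,221658_s_at,IL21,
TNFRSF1A,TNF,RECEPTOR,241944_x_at,TNF,
TNFRSF13B,TNF,RECEPTOR,207641_at,TNFSF13B,
TNFRSF13C,TNF,RECEPTOR,,TNFSF13B,
TNFRSF17,TNF,RECEPTOR,206641_at,TNFSF13,
EGFR,EGF,RECEPTOR,211551_at,,
ERBB2,EGF,RECEPTOR,216836_s_at,,
ERBB3,EGF,RECEPTOR,202454_s_at,,
ERBB4,EGF,RECEPTOR,214053_at,,
FLT1,VEGF,RECEPTOR,,,
KDR,VEGF,RECEPTOR,,,
FLT4,VEGF,RECEPTOR,,,
FGFR1,FGF,RECEPTOR,,,
FGFR2,FGF,RECEPTOR,,,
FGFR3,FGF,RECEPTOR,204379_s_at,,
FGFR4,FGF,RECEPTOR,,,
FZD1,WNT,RECEPTOR,204451_at,,
FZD2,WNT,RECEPTOR,210220_at,,
FZD3,WNT,RECEPTOR,219683_at,,
FZD4,WNT,RECEPTOR,218665_at,,
FZD5,WNT,RECEPTOR,,,
FZD6,WNT,RECEPTOR,203987_at,,
FZD7,WNT,RECEPTOR,203706_s_at,,
FZD8,WNT,RECEPTOR,227405_s_at,,
FZD9,WNT,RECEPTOR,,,
FZD10,WNT,RECEPTOR,,,
LRP5,WNT,RECEPTOR,,,
LRP6,WNT,RECEPTOR,225745_at,,
NOTCH1,OTHER,RECEPTOR,218902_at,,
NOTCH2,OTHER,RECEPTOR,212377_s_at,,
NOTCH3,OTHER,RECEPTOR,203238_s_at,,
NOTCH4,OTHER,RECEPTOR,205247_at,,
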