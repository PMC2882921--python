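gene,probe_set,median,range_min,range_max,presence_pct
IGF1R,203627_at,19,1,85,32
MET,203510_at,78,4,728,50
CCR1,205098_at,136,26,2840,78
PTPRZ1,204469_at,24,1,1958,48
NTRK2,207152_at,84,4,286,77
IL6R,205945_at,502,7,3657,99
IL6ST,212195_at,1681,210,5680,100
OSMR,205729_at,25,1,88,58
LIFR,225575_at,16,1,203,15
IL11RA,204773_at,61,3,140,26
CRLF1,206315_at,15,2,91,0
IL1R1,202948_at,10,1,63,1
IL10RA,204912_at,212,24,912,92
IL10RB,209575_at,240,98,536,100
IL15RA,207375_s_at,142,16,403,55
IL21R,221658_s_at,6,1,395,5
TNFRSF1A,241944_x_at,63,4,233,66
TNFRSF13B,207641_at,266,50,745,95
TNFRSF17,206641_at,3794,968,8301,100
EGFR,211551_at,56,6,148,64
ERBB2,216836_s_at,30,2,106,5
ERBB3,202454_s_at,47,79,172,59
ERBB4,214053_at,51,2,1091,38
FGFR3,204379_s_at,4.2,1,13160,10
FZD1,204451_at,75,2,586,34
FZD2,210220_at,30,1,680,30
FZD3,219683_at,80,15,465,19
FZD4,218665_at,84,2,348,92
FZD6,203987_at,229,6,1425,
FZD7,203706_s_at,102,12,2228,98
FZD8,227405_s_at,34,3,338,93
LRP6,225745_at,70,1,137,43
NOTCH1,218902_at,85,24,233,47
NOTCH2,212377_s_at,216,43,1743,100
NOTCH3,203238_s_at,28,1.4,95,2
NOTCH4,205247_at,40,8,190,35
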