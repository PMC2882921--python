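gene,family,role,probe_sets,receptor_of,also_family
IGF1,KNOWN_MGF,LIGAND,209541_at,,
HGF,KNOWN_MGF,LIGAND,210997_at,,
CCL3,KNOWN_MGF,LIGAND,205114_s_at,,
GDF15,KNOWN_MGF,LIGAND,221577_x_at,,
PTN,KNOWN_MGF,LIGAND,209466_x_at,,
BDNF,KNOWN_MGF,LIGAND,206382_s_at,,
IL6,KNOWN_MGF,LIGAND,205207_at,,
CNTF,KNOWN_MGF,LIGAND,,,
OSM,KNOWN_MGF,LIGAND,230170_at,,
LIF,KNOWN_MGF,LIGAND,205266_at,,
IL11,KNOWN_MGF,LIGAND,,,
CLCF1,KNOWN_MGF,LIGAND,219500_at,,
IL1B,KNOWN_MGF,LIGAND,39402_at,,
IL10,KNOWN_MGF,LIGAND,207433_at,,
IL15,KNOWN_MGF,LIGAND,205992_s_at,,
IL21,KNOWN_MGF,LIGAND,,,
TNF,KNOWN_MGF,LIGAND,207113_s_at,,
TNFSF13B,KNOWN_MGF,LIGAND,223501_at,,
TNFSF13,KNOWN_MGF,LIGAND,210314_x_at,,
AREG,KNOWN_MGF,LIGAND,205239_at,,
HBEGF,KNOWN_MGF,LIGAND,203821_at,,
NRG1,KNOWN_MGF,LIGAND,208241_at,,
NRG2,KNOWN_MGF,LIGAND,206879_s_at,,
NRG3,KNOWN_MGF,LIGAND,229233_at,,
NRG4,KNOWN_MGF,LIGAND,242426_at,,
FGF2,KNOWN_MGF,LIGAND,204422_s_at,,FGF
WNT5A,KNOWN_MGF,LIGAND,205990_s_at,,WNT
WNT10B,KNOWN_MGF,LIGAND,,,WNT
WNT16,KNOWN_MGF,LIGAND,224022_x_at,,WNT
JAG1,KNOWN_MGF,LIGAND,209099_x_at,,
JAG2,KNOWN_MGF,LIGAND,32137_at,,
VEGFA,KNOWN_MGF,LIGAND,212171_x_at,,VEGF
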