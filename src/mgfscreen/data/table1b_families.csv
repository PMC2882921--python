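gene,family,role,probe_sets,receptor_of,also_family
VEGFA,VEGF,LIGAND,212171_x_at,,
VEGFB,VEGF,LIGAND,203683_s_at,,
VEGFC,VEGF,LIGAND,209946_at,,
FIGF,VEGF,LIGAND,,,
FGF1,FGF,LIGAND,1552721_a_at,,
FGF2,FGF,LIGAND,204422_s_at,,
FGF3,FGF,LIGAND,214571_at,,
FGF4,FGF,LIGAND,206783_at,,
FGF5,FGF,LIGAND,210311_at,,
FGF6,FGF,LIGAND,208417_at,,
FGF7,FGF,LIGAND,230918_at,,
FGF8,FGF,LIGAND,,,
FGF9,FGF,LIGAND,206404_at,,
FGF10,FGF,LIGAND,,,
FGF11,FGF,LIGAND,227271_at,,
FGF12,FGF,LIGAND,1562794_at,,
FGF13,FGF,LIGAND,205110_s_at,,
FGF14,FGF,LIGAND,231523_at,,
FGF16,FGF,LIGAND,,,
FGF17,FGF,LIGAND,,,
FGF18,FGF,LIGAND,231382_at,,
FGF19,FGF,LIGAND,,,
FGF20,FGF,LIGAND,,,
FGF21,FGF,LIGAND,,,
FGF22,FGF,LIGAND,,,
FGF23,FGF,LIGAND,,,
WNT1,WNT,LIGAND,,,
WNT2,WNT,LIGAND,205648_at,,
WNT2B,WNT,LIGAND,,,
WNT3,WNT,LIGAND,229103_at,,
WNT3A,WNT,LIGAND,,,
WNT4,WNT,LIGAND,208606_s_at,,
WNT5A,WNT,LIGAND,205990_s_at,,
WNT5B,WNT,LIGAND,221029_s_at,,
WNT6,WNT,LIGAND,71933_at,,
WNT7A,WNT,LIGAND,210248_at,,
WNT7B,WNT,LIGAND,,,
WNT8A,WNT,LIGAND,224259_at,,
WNT8B,WNT,LIGAND,,,
WNT9A,WNT,LIGAND,,,
WNT9B,WNT,LIGAND,,,
WNT10A,WNT,LIGAND,223709_s_at,,
WNT10B,WNT,LIGAND,,,
WNT11,WNT,LIGAND,206737_at,,
WNT16,WNT,LIGAND,224022_x_at,,
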