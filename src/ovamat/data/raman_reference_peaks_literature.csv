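label,position,note
collagen,855,proline ring / C-C backbone
collagen,876,hydroxyproline
collagen,938,C-C protein backbone
collagen,1246,amide III
collagen,1450,CH2 deformation
collagen,1668,amide I
GAG,898,C-O-C glycosidic
GAG,1041,C-O / C-C stretch
GAG,1063,sulfate / C-O stretch
GAG,1126,C-O-C ring
GAG,1375,CH3 symmetric (acetyl)
GAG,1412,COO- symmetric stretch
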