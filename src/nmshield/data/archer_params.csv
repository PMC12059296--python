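nuclide,material,alpha,beta,gamma,source
Tc-99m,lead,2.558,1.010,4.344,this report
Tc-99m,gypsum,0.009549,-0.005312,1.430,this report
Tc-99m,lw_concrete,0.02047,-0.01122,0.4389,this report
Tc-99m,nw_concrete,0.03102,-0.01729,0.3622,this report
Tc-99m,a514_steel,0.1581,-0.04346,0.2602,this report
Tc-99m,glass,0.03419,-0.02009,0.3076,this report
Lu-177,lead,0.3855,1.071,0.2822,this report
Lu-177,gypsum,0.009594,-0.003783,0.3739,this report
Lu-177,lw_concrete,0.01615,-0.007056,0.5194,this report
Lu-177,nw_concrete,0.02477,-0.01173,0.4404,this report
Lu-177,a514_steel,0.0797,2.243,28.74,this report
Lu-177,glass,0.02456,-0.01197,0.6480,this report
I-131,lead,0.1082,0.2072,0.5385,this report
I-131,lw_concrete,0.01363,-0.007896,0.4847,this report
I-131,nw_concrete,0.02062,-0.01220,0.4179,this report
I-131,a514_steel,0.05786,-0.02574,0.8742,this report
I-131,glass,0.02191,-0.01319,0.4497,this report
F-18,lead,0.166,-0.02184,0.2436,this report
F-18,lw_concrete,0.01126,-0.006463,0.7475,this report
F-18,nw_concrete,0.01558,-0.008775,0.8600,this report
F-18,a514_steel,0.05032,-0.02632,1.223,this report
F-18,lead,0.1543,-0.04406,2.133,TG-108
F-18,nw_concrete,0.01539,-0.01161,2.076,TG-108
F-18,iron,0.05705,-0.03063,0.6319,TG-108
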