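extract,dpph_umol_te_g,tpc_mg_gae_g
allspice,555,31.61
basil,134.7,14.81
bay leaf,231.9,22.56
black seed,7.59,2.46
cardamom,5.45,1.24
caraway,20.2,2.39
clove,1443,167.2
garlic,14.8,3.6
nutmeg,22.22,3.89
onion,5.74,7.05
oregano,171.6,20.7
rosemary,50.4,4.66
thyme,278.3,23.5
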