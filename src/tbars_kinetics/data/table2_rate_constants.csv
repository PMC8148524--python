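extract,temperature_k,k_mean,k_sd
control,277,0.14672,0.00218
control,281,0.20124,0.00371
control,289,0.40969,0.00084
control,293,0.61344,0.00387
allspice,277,0.01624,0.00039
allspice,281,0.05191,0.00096
allspice,289,0.17147,0.00998
allspice,293,0.29703,0.00748
basil,277,0.05460,0.00152
basil,281,0.09710,0.00032
basil,289,0.35292,0.00162
basil,293,0.47148,0.01188
bay leaf,277,0.02326,0.00205
bay leaf,281,0.05404,0.00100
bay leaf,289,0.11087,0.01111
bay leaf,293,0.22333,0.00295
black seed,277,0.02269,0.00135
black seed,281,0.07358,0.00136
black seed,289,0.31358,0.01153
black seed,293,0.54074,0.00553
cardamom,277,0.07303,0.00326
cardamom,281,0.12740,0.00235
cardamom,289,0.28783,0.00216
cardamom,293,0.46826,0.01179
caraway,277,0.09533,0.00176
caraway,281,0.11328,0.00406
caraway,289,0.14559,0.00501
caraway,293,0.20404,0.00165
clove,277,0.06834,0.00007
clove,281,0.08858,0.00006
clove,289,0.15796,0.00925
clove,293,0.23645,0.00026
garlic,277,0.11126,0.00131
garlic,281,0.14729,0.00165
garlic,289,0.33049,0.01478
garlic,293,0.49409,0.00183
nutmeg,277,0.06435,0.00119
nutmeg,281,0.09282,0.00171
nutmeg,289,0.20392,0.01146
nutmeg,293,0.26457,0.00666
onion,277,0.11100,0.00017
onion,281,0.16893,0.00311
onion,289,0.53441,0.00765
onion,293,0.69916,0.01761
oregano,277,0.04735,0.00112
oregano,281,0.10165,0.00196
oregano,289,0.34245,0.00984
oregano,293,0.59431,0.01997
rosemary,277,0.05135,0.00103
rosemary,281,0.14071,0.00083
rosemary,289,0.43025,0.01579
rosemary,293,0.49277,0.00029
thyme,277,0.06746,0.00031
thyme,281,0.11290,0.00054
thyme,289,0.30439,0.00057
thyme,293,0.39286,0.00182
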