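extract,r2_arrhenius,r2_arrhenius_sd,ea_j_mol,ea_sd,k0_per_day,k0_sd,r2_loglogistic,r2_loglogistic_sd,c_per_degc,c_sd,tc_degc,tc_sd
control,0.9972,0.0005,60292,863,1.7e11,3.8e10,0.9955,0.0010,0.1094,0.0015,21.73,0.08
allspice,0.9794,0.0011,118544,1355,4.7e20,2.8e20,0.9973,0.0009,0.1615,0.0027,26.53,0.13
basil,0.9896,0.0018,94708,168,3.9e16,2.6e15,0.9786,0.0046,0.1357,0.0023,23.36,0.25
bay leaf,0.9718,0.0121,88610,4357,3.37e15,4.7e15,0.9779,0.0176,0.1495,0.0009,29.48,0.52
black seed,0.9857,0.0025,131842,1783,2.2e23,1.3e23,0.9971,0.0015,0.1827,0.0035,21.74,0.06
cardamom,0.9972,0.0006,76564,935,2.1e13,7.1e12,0.9966,0.0015,0.1288,0.0013,24.13,0.25
caraway,0.8868,0.0228,27250,140,1.4e4,8.3e2,0.8832,0.0222,0.0442,0.0006,54.87,0.12
clove,0.9891,0.0099,-122721,646,3.8e8,1.5e8,0.9867,0.0145,0.1514,0.0034,57.87,0.12
garlic,0.9941,0.0010,63945,821,1.2e11,3.9e10,0.9963,0.0031,0.1121,0.0008,24.11,0.10
nutmeg,0.9965,0.0035,61056,898,2.2e10,9.9e9,0.9929,0.0073,0.0932,0.0008,32.57,0.41
onion,0.9979,0.0003,79215,406,8.9e13,1.6e13,0.9948,0.0024,0.1433,0.0019,20.09,0.25
oregano,0.9963,0.0003,105249,177,3.5e18,5.7e17,0.9996,0.0001,0.1695,0.0007,21.24,0.21
rosemary,0.9495,0.0056,95558,1110,6.9e16,3.3e16,0.9957,0.0016,0.1024,0.0018,28.75,0.57
thyme,0.9916,0.0004,76348,195,1.7e13,1.4e12,0.9840,0.0004,0.1123,0.0005,26.09,0.07
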