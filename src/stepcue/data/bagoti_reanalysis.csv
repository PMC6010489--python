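ant,n_steps,D_hat,logl_gse,logl_biexp,logl_gse_free,w_gse_vs_biexp,w_gse_vs_free
1,12,2.03,-22.38,-23.37,-22.06,0.82,0.82
2,21,1.63,-27.10,-26.73,-26.89,0.73,0.76
3,21,1.44,-20.48,-20.19,-20.46,0.74,0.79
4,28,2.16,-28.09,-28.10,-28.00,0.78,0.76
5,30,1.64,-32.94,-32.79,-32.76,0.74,0.74
6,20,1.64,-27.79,-25.84,-27.67,0.36,0.66
7,34,1.74,-31.92,-31.28,-31.47,0.63,0.68
8,18,2.19,-17.36,-17.47,-16.91,0.82,0.73
9,13,1.55,-16.06,-13.48,-15.10,0.30,0.68
10,26,1.30,-19.83,-17.46,-19.61,0.35,0.81
11,29,1.66,-23.48,-23.05,-23.06,0.69,0.75
12,16,1.85,-26.91,-25.70,-25.99,0.58,0.65
13,2,,,,,,
14,17,1.73,-33.36,-31.89,-33.33,0.51,0.61
15,20,1.77,-25.40,-23.45,-24.60,0.36,0.64
16,28,2.00,-34.12,-35.10,-34.10,0.77,0.78
17,23,1.34,-4.42,-1.89,-3.91,0.23,0.57
18,10,1.40,-16.49,-16.54,-16.47,0.90,0.89
19,41,1.91,-37.04,-36.01,-36.67,0.53,0.69
20,29,1.00,-23.27,-22.95,-22.52,0.71,0.62
21,45,1.02,-49.19,-49.06,-48.33,0.73,0.57
22,49,1.74,-49.24,-49.92,-49.20,0.86,0.75
23,44,1.76,-48.77,-44.41,-48.41,0.69,0.69
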