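layer,vlo,vlo_se,vlo_n,vlo_r2,jmo,jmo_se,jmo_n,jmo_r2
1,20.31,2.57,5,0.88,50.83,10.69,5,0.73
3,32.82,7.70,5,0.66,67.49,14.66,5,0.67
5,56.08,7.09,5,0.73,72.62,14.08,5,0.73
7,68.56,6.88,5,0.69,88.63,12.47,5,0.69
9,71.25,5.60,5,0.80,107.64,11.84,5,0.75
11,77.93,6.24,5,0.70,119.64,9.87,5,0.85
13,81.72,5.74,5,0.83,123.97,9.77,5,0.78
15,88.62,8.20,5,0.76,175.42,13.17,5,0.71
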