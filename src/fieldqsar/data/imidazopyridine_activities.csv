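id,ki_nm,set,pki,pred_comfa,pred_comsia,pred_topomer,pharm_model
1,60.0,train,7.222,7.240,7.269,7.190,0
2,25.0,test,7.602,7.494,7.529,7.490,0
3,130.0,train,6.886,6.941,6.937,7.020,0
4,140.0,train,6.854,6.854,6.935,6.920,0
5,180.0,test,6.745,6.843,6.916,6.920,0
6,68.0,train,7.167,7.154,7.162,7.170,0
7,510.0,train,6.292,6.324,6.327,6.330,0
8,830.0,train,6.081,6.080,6.080,6.090,0
9,487.0,train,6.312,6.324,6.316,6.320,0
10,56.0,train,7.252,7.150,7.165,7.180,0
11,58.0,train,7.237,7.278,7.158,7.220,0
12,730.0,train,6.137,6.094,6.100,6.080,0
13,78.4,train,7.106,7.159,7.172,7.230,0
14,27.2,train,7.565,7.447,7.415,7.460,1
15,364.0,test,6.439,6.307,6.539,6.420,0
16,116.0,train,6.936,6.982,6.981,7.030,0
17,44.0,train,7.357,7.405,7.409,7.380,1
18,36.5,train,7.438,7.389,7.547,7.580,1
19,87.5,test,7.058,7.253,7.268,7.310,0
20,55.1,train,7.259,7.214,7.216,7.220,0
21,43.0,train,7.367,7.306,7.342,7.320,1
22,37.0,train,7.432,7.546,7.573,7.480,1
23,308.7,test,6.510,6.651,6.419,6.540,0
24,20.9,test,7.680,7.663,7.657,7.740,1
25,39.0,train,7.409,7.372,7.369,7.410,0
26,24.0,train,7.620,7.626,7.628,7.560,1
27,72.0,train,7.143,7.177,7.209,7.170,0
28,22.8,test,7.642,7.568,7.594,7.390,1
29,62.7,train,7.203,7.199,7.150,7.160,0
30,48.0,train,7.319,7.347,7.399,7.260,1
31,86.3,train,7.064,7.029,6.999,6.970,0
32,67.0,test,7.174,7.191,7.195,7.070,0
zolpidem,44.0,train,7.357,7.359,7.349,7.260,1
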