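id,dEvdw_kJmol,dEele_kJmol,dGpb_kJmol,dGsa_kJmol,dGbind_kJmol,dEvdw_sd,dEele_sd,dGpb_sd,dGsa_sd,dGbind_sd
zolpidem,-166.722,-12.403,102.850,-18.907,-95.181,2.866,5.571,2.345,0.636,6.696
14,-185.718,-33.782,117.687,-18.241,-120.055,5.400,4.775,6.308,0.582,6.238
DS03,-187.731,-14.533,94.581,-18.692,-126.376,10.951,4.779,4.630,0.655,11.440
DS04,-183.268,-45.446,116.936,-19.729,-131.507,8.895,6.257,7.296,0.823,10.246
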