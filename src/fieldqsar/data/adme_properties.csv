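id,mw,logp,fraction_csp3,rotatable_bonds,tpsa,water_solubility,caco2,hia,skin_permeability,gi_absorption,pgp_substrate,bbb_permeant,cns_log_ps,cyp2d6_substrate,cyp3a4_substrate,cyp2d6_inhibitor,cyp3a4_inhibitor,total_clearance,renal_oct2_substrate,herg_inhibitor,skin_sensitization,lipinski_violations,synthetic_accessibility
DS01,364.42,2.861,0.29,5,69.09,-3.076,1.217,94.438,-2.725,High,No,Yes,-1.054,No,No,No,No,0.762,No,No,No,0,3.24
DS02,390.94,3.853,0.37,5,69.09,-3.091,1.008,95.073,-2.735,High,No,Yes,-1.035,No,No,No,No,0.842,No,No,No,0,3.46
DS03,376.91,3.540,0.33,5,69.09,-3.094,1.003,94.320,-2.735,High,No,Yes,-1.307,No,No,No,No,0.848,No,No,No,0,3.35
DS04,377.47,3.785,0.36,8,69.09,-3.357,1.445,96.052,-2.735,High,No,Yes,-1.295,No,No,No,No,0.894,No,No,No,0,3.27
zolpidem,307.39,3.248,0.26,3,37.61,-3.586,0.977,95.252,-2.735,High,No,Yes,-1.125,No,No,No,No,0.722,Yes,No,No,0,2.93
14,311.36,3.475,0.22,4,46.40,-3.405,1.321,94.089,-2.735,High,No,Yes,-1.265,No,No,No,No,0.886,Yes,No,No,0,2.72
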