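id,docking_score,predicted_pki
14,6.910,7.460
DS01,9.035,7.643
DS02,9.036,7.645
DS03,9.776,7.689
DS04,9.262,7.678
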