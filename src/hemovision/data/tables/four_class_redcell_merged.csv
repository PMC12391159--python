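ground_truth,red cell,leukocyte,platelet,non_detected
red cell,757,7,13,76
leukocyte,3,116,0,26
platelet,13,2,148,11
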