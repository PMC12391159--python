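ground_truth,echinocyte,erythrocyte,leukocyte,platelet,non_detected
echinocyte,429,43,6,6,58
erythrocyte,24,261,1,7,18
leukocyte,1,2,116,0,26
platelet,8,5,2,148,11
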