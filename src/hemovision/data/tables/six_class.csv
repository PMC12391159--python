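ground_truth,echinocyte,erythrocyte,lymphocyte,monocyte,neutrophil,platelet,non_detected
echinocyte,14174,5235,929,119,45,488,0
erythrocyte,1457,10278,837,146,60,142,0
lymphocyte,46,202,1955,77,62,7,0
monocyte,31,71,94,954,69,9,0
neutrophil,6,23,133,246,1314,0,0
platelet,154,129,6,0,0,4609,57
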