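ground_truth,red cell,leukocyte,platelet,non_detected
red cell,30864,2074,839,2
leukocyte,448,4906,19,0
platelet,250,1,4737,73
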