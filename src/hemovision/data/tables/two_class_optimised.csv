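ground_truth,echinocyte,erythrocyte,non_detected
echinocyte,81,15,2
erythrocyte,9,232,1
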