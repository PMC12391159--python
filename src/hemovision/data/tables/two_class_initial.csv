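ground_truth,echinocyte,erythrocyte,non_detected
echinocyte,408,66,56
erythrocyte,29,349,9
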