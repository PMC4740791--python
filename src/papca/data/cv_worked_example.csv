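condition,sample,truth,cycle1_slope,cycle1_mid,cycle1_both,cycle2_slope,cycle2_mid,cycle2_both,cycle3_slope,cycle3_mid,cycle3_both
normal,1,1,1,1,1,1,1,1,1,3,1
normal,2,1,1,2,1,2,1,1,1,2,1
normal,3,1,1,1,1,2,1,1,1,1,1
normal,4,1,1,1,1,1,1,1,1,1,1
steatosis,5,2,2,2,2,2,1,1,2,2,2
steatosis,6,2,2,2,2,2,3,2,2,1,2
steatosis,7,2,2,2,2,2,1,2,2,1,2
steatosis,8,2,2,3,2,2,3,2,1,1,1
fibrosis,9,3,3,3,3,3,3,3,3,3,3
fibrosis,10,3,1,3,3,3,1,3,3,1,3
fibrosis,11,3,3,1,3,3,1,3,1,1,1
fibrosis,12,3,3,2,3,3,3,3,2,1,1
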