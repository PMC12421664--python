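basis_family,cardinal_low,cardinal_high,alpha,beta
cc,2,3,4.420,2.460
cc,3,4,5.460,3.050
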