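semester,complied_n,ipsi_n
1,744,123
2,570,58
3,499,79
4,141,53
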