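quadrant,focal,generalized,unknown
High-Low,6,3,5
High-High,11,4,4
Normal-High,26,14,10
Normal-Low,27,16,13
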