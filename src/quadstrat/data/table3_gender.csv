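quadrant,male,female
High-Low,10,4
High-High,8,11
Normal-High,22,28
Normal-Low,20,36
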