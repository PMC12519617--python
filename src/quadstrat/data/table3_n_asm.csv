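quadrant,0,1,2,3,4,5
High-Low,1,9,2,1,0,1
High-High,2,6,6,3,2,0
Normal-High,7,29,9,4,1,0
Normal-Low,2,34,17,3,0,0
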