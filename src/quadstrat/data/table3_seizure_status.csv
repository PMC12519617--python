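quadrant,recent,intermediate,seizure_free
High-Low,6,2,6
High-High,13,3,3
Normal-High,20,7,23
Normal-Low,18,4,34
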