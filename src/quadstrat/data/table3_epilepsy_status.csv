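quadrant,DRE,undetermined,WCE
High-Low,4,4,6
High-High,11,5,3
Normal-High,10,21,19
Normal-Low,11,20,25
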