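group,validated,not_validated
1,4,4
2,2,0
3,29,4
4,2,0
5,9,0
6,13,2
Normal,9,16
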