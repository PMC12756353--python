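group,validated,not_validated
+,28,3
-,0,2
N,36,9
/,0,16
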