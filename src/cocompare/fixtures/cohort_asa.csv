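asa_class,count
1,8
2,45
3,2
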