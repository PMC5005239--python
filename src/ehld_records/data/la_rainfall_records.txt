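21.26
11.35
10.40
9.21
6.73
5.59
5.58
4.85
4.42
3.21
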