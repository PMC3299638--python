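GeneRuler 1kb
14
10000
8000
6000
5000
4000
3500
3000
2500
2000
1500
1000
750
500
250
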