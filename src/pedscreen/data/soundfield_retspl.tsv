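frequency	retspl_db
500	4
1000	2
2000	-1
4000	-5
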