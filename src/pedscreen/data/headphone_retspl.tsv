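frequency	retspl_db
500	11
1000	1
2000	3
4000	-2
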