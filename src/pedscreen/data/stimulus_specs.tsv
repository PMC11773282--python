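name	category	center_freq	band_low	band_high	slope	duration
drum	noisemaker	500	250	750	24	2.5
horn	environmental	500	250	750	24	2.5
cow_mooing	animal	500	250	750	24	2.5
wooden_rattle	noisemaker	1000	750	1250	24	2.5
applause	environmental	1000	750	1250	24	2.5
dog_barking	animal	1000	750	1250	24	2.5
metallic_rattle	noisemaker	2000	1750	2250	24	2.5
laughing	environmental	2000	1750	2250	24	2.5
horse_whinny	animal	2000	1750	2250	24	2.5
bell	noisemaker	4000	3750	4250	24	2.5
telephone_ring	environmental	4000	3750	4250	24	2.5
bird_chirp	animal	4000	3750	4250	24	2.5
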