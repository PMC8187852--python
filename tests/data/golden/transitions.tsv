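direction	count	rate	rate_error
folded->unfolded	5	0.03140703518	0.01404565312
unfolded->folded	3	0.01884422111	0.01087971613
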