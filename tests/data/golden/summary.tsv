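n_frames	nf_eff	nf_eff_fraction
400	287.6585573	0.7191463934
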