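state	population	error
folded	0.2639998857	0.1234717364
misfolded	0.2348219102	0.1180806611
unfolded	0.5011782041	0.224756797
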