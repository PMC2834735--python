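# attractant-removal step response of the headline band-pass controller
controller: {type: filter, kind: band_pass, A: 16.0, omega1: 0.02, omega2: 5.0, rank: 2, sign: attractant}
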