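# 100-agent base config for cut-off frequency scans (use with `taxisim scan`)
controller: {type: filter, kind: band_pass, A: 16.0, omega1: 0.02, omega2: 5.0, rank: 2, sign: attractant}
field: {shape: mountain, L0: 2.0, r: 2.0}
simulation: {n_bacteria: 100, duration: 1000.0, dt: 0.5, speed: 0.02, init_position: [1.4, 0.0], seed: 0}
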