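# non-adaptive comparator: high-gain, high-cut-off low-pass controller
controller: {type: filter, kind: low_pass, A: 64.0, omega0: 5.0, sign: attractant}
field: {shape: mountain, L0: 2.0, r: 2.0}
simulation: {n_bacteria: 100, duration: 1000.0, dt: 0.5, speed: 0.02, init_position: [1.4, 0.0], seed: 0}
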