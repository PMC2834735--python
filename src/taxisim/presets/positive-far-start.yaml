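# positive designed pathway started farther down the gradient (3.5 mm)
controller: {type: pathway, variant: positive, K_L: 1.0}
field: {shape: mountain, L0: 2.0, r: 2.0}
simulation: {n_bacteria: 2000, duration: 1000.0, dt: 0.5, speed: 0.02, init_position: [3.5, 0.0], seed: 0}
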