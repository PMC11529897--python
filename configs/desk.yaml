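# Desk-scale setup: width-32 networks, 30 epochs with the published stage
# proportions (transition 30%->45% of training, warm-up first quarter).
gan: {ngf: 32, ndf: 32}
optim: {pretrain_epochs: 8, seed: 1}
schedule: {T_s: 9, T_e: 14, T_m: 30}
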