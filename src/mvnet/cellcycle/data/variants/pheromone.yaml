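# mating-pheromone treatment: the alpha-factor signal clamped to 9
name: pheromone
signal_settings: {alpha-factor: 9}
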