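name: hcm1_by_clb5cdk
structural_variants: [hcm1_by_clb5cdk]
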