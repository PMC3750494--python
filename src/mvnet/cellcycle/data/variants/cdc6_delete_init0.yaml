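# cdc6 deletion with no pre-existing store: immediate arrest before S.
name: cdc6_delete_init0
knockouts: [CDC6]
initial_overrides: {CDC6: 0, Cdc6: 0}
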