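# cdc6 deletion in a cell that still carries its telophase store of CDC6
# RNA and Cdc6 protein (both start at 9): one more round of replication
# is possible before arrest.
name: cdc6_delete_init9
knockouts: [CDC6]
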