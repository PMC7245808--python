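# Default HLGT pre-filter: the two high level group terms used to build
# the annotation dataset.
Device issues
Medication errors, and other product use errors and issues
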