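# Negation cues: text indicating the consumer had NOT performed the
# sought drug administration error. Sentence-scoped cue matching, not
# full scope resolution.
did not
does not
denied
denies
never
without using
no longer
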