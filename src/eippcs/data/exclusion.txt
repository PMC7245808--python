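# Exclusion cues: reports originating from inhaled-insulin clinical
# trials are out of scope for this error.
inhaled insulin
inhaler
inhalation
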