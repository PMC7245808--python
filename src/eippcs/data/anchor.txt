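# Anchor terms: the error by definition involves a syringe.
# Explicit surface variants; no stemming is applied anywhere.
syringe
syringes
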