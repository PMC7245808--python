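# Action-verb vocabulary for the I2E co-occurrence rule: verbs that,
# when present in the same sentence as the word "syringe", can be
# descriptive of the error. Explicit inflected forms; no stemming.
inject
injected
injecting
administer
administered
administering
use
used
using
withdraw
withdrew
withdrawn
extract
extracted
extracting
draw
drew
drawn
mix
mixed
mixing
take
taking
took
transfer
transferred
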