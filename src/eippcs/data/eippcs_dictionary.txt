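# EIPPCS dictionary: words and short phrases descriptive of extracting
# insulin from a prefilled pen or cartridge. Multiword entries matter:
# longest-match tagging lets "withdrew insulin" span two tokens, which
# tightens the word gap measured to the anchor.
withdrew
withdrew insulin
withdraw
withdraw insulin
withdrawn
withdrawing
drew up
draw up
drawn up
drawing up
extract
extracted
extracting
extraction
mix
mixed
mixing
mixed in
transfer
transferred
transferring
taking insulin
take insulin
took insulin
aspirated
removed insulin
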