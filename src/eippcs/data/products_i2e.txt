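# Product vocabulary for the default I2E ruleset. Deliberately omits the
# FlexTouch-like brand "dosetouch": the published query missed cases on a
# product that was not part of it, and the default ruleset reproduces
# that miss mechanism.
pen
pens
prefilled pen
cartridge
cartridges
penfill
flexpen
novopen
novolog
novorapid
levemir
glarpen
rapidfill
mixopen
basalfill
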