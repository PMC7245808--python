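# Insulin pen/cartridge product vocabulary for the CPR pipeline:
# marketed pen product names plus generic device words, plus the
# fictional brands used by the synthetic corpus generator.
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
dosetouch
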