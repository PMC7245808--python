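# The 12 MedDRA preferred terms used as the second filter of the SSA method.
Device failure
Device malfunction
Device use error
Device use issue
Drug administered in wrong device
Drug administration error
Intentional device misuse
Intentional product misuse
Product use issue
Wrong device used
Wrong technique in device usage process
Wrong technique in product usage process
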