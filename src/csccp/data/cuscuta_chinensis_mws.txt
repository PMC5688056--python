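# Cuscuta chinensis: neutral target masses (Da) from the LC-MS peak table
286.24
302.24
354.31
478.41
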