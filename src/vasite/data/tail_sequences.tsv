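# Brain tubulin isotype C-terminal tail sequences (one-letter codes).
isotype	sequence
TUBA1A	DYEEVGVDSVEGEEEGEEY
TUBA1C	DYEEVGADSADGEDEGEEY
TUBA4A	DYEEVGIDSYEDEDEGEE
TUBB	DATAEEEEDFGEEAEEEA
TUBB2A/TUBB2B	DATADEQGEFEEEEGEDEA
TUBB2C	DATAEEEGEFEEEAEEEVA
TUBB3	DATAEEEGEMYEDDEEESEAQGPK
TUBB4	DATAEQGEFEEEAEEEVA
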