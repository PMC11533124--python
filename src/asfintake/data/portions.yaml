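# Standardized portion sizes (grams per serving) used to convert g/d
# into servings per day or week. Editable; override via the CLI or API.
milk: 245
cheese: 42
yogurt: 245
eggs: 55
seafood: 100
unprocessed_red_meat: 100
processed_meat: 50
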