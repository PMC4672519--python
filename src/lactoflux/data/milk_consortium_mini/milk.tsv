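metabolite	max_uptake
biotin	1
lactose	10
milk_peptides	10
nicotinate	1
pantothenate	1
phosphate	10
pyridoxamine	1
riboflavin	1
thiamin	1
water	1000
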