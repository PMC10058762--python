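group,low,high
cereals_tubers,250,400
vegetables,300,500
fruits,200,350
meat,40,75
aquatic_products,40,75
soybean_nuts,25,35
eggs,40,50
dairy,300,500
edible_oil,25,30
salt,0,5
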