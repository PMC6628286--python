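item_name,teac_content,is_coffee
apple,4.0,0
orange,9.0,0
strawberries,25.0,0
red_wine,20.0,0
coffee,25.0,1
spinach,12.0,0
tomato,5.0,0
legumes,8.0,0
olive_oil,3.0,0
walnuts,85.0,0
dark_chocolate,50.0,0
orange_juice,6.0,0
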