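parameter_name,global_mean,global_sd,effect_score
carbohydrate,140.0,25.0,0.097
protein,40.0,8.0,0.021
total_fat,38.0,8.0,0.298
alcohol,6.0,6.0,-0.278
fiber,12.0,4.0,-0.663
cholesterol,150.0,60.0,0.110
saturated_fat,13.0,4.0,0.373
monounsaturated_fat,15.0,5.0,-0.009
polyunsaturated_fat,7.0,3.0,-0.337
vitamin_a,450.0,300.0,-0.401
vitamin_b1,0.8,0.25,-0.098
vitamin_b2,0.9,0.3,-0.068
vitamin_b3,10.0,3.0,-0.246
vitamin_b6,0.9,0.3,-0.365
vitamin_b12,3.0,2.0,0.106
vitamin_c,60.0,35.0,-0.424
vitamin_d,2.5,1.5,-0.446
vitamin_e,5.0,2.0,-0.419
folic_acid,150.0,60.0,-0.19
iron,7.0,2.0,0.032
magnesium,150.0,40.0,-0.484
zinc,5.0,1.5,-0.313
anthocyanidins,10.0,8.0,-0.131
flavan3ols,30.0,25.0,-0.415
flavones,1.0,0.8,-0.616
flavonols,10.0,6.0,-0.467
flavonones,15.0,12.0,-0.25
isoflavones,0.5,0.6,-0.593
garlic,2.0,2.0,-0.412
onion,15.0,10.0,-0.301
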