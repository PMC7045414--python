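site_id,nutrient_class,C_percent,N_total_mg_g,P_total_mg_kg,K_total_mg_kg,Ca_total_mg_kg,P_extractable_mg_kg
High 1,high,4.44,3.23,150.5,571.0,283.1,9.90
High 2,high,4.06,3.57,140.8,8853.7,1344.6,5.03
High 3,high,3.65,3.42,192.2,6393.0,377.0,5.15
High 4,high,4.71,3.68,198.9,4709.7,283.3,6.27
High 5,high,4.76,3.51,122.5,3057.7,425.1,4.73
High 6,high,5.37,3.01,123.6,317.0,64.0,5.12
Low 1,low,2.23,0.93,56.3,568.1,243.7,4.52
Low 2,low,1.32,0.74,48.7,1924.8,27.9,3.16
Low 3,low,1.20,0.69,45.1,292.4,88.8,1.67
Low 4,low,1.74,0.81,51.7,2143.4,59.3,3.48
Low 5,low,1.10,0.71,15.9,1154.4,76.8,0.65
Low 6,low,1.24,0.78,44.2,1052.9,27.8,2.57
Greenhouse,greenhouse,10.27,1.85,50.6,1281.9,2269.1,12.36
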