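nutrient,window,start_month,end_month,mean,sd,min,max,unit
Copper,1,6,20,0.6,0.2,0.2,1.1,mg/day
Folate,1,6,20,179.9,85.3,29.3,459.1,mcg/day
Histidine,1,6,20,0.2,0.1,0,0.7,g/day
Iron,1,6,20,9,5.2,0.6,23,mg/day
Isoleucine,1,6,20,0.4,0.3,0,1.2,g/day
Leucine,1,6,20,0.8,0.6,0,3.1,g/day
Magnesium,1,6,20,144.6,54.8,33.2,295,mg/day
Phosphorus,1,6,20,688,235.1,163.8,1349.4,mg/day
Potassium,1,6,20,1281.2,548.7,131,3268.1,mg/day
Selenium,1,6,20,55.1,25.9,6.2,150,mcg/day
Valine,1,6,20,0.5,0.4,0,1.5,g/day
Vitamin A,1,6,20,453.3,344.5,30.6,2597.6,mcg/day
Vitamin B1,1,6,20,0.8,0.4,0,1.7,mg/day
Vitamin B2,1,6,20,1.3,0.5,0.3,2.5,mg/day
Vitamin B6,1,6,20,1,0.6,0.2,4,mg/day
3'SL,1,6,20,15.3,17.3,0,54.6,mg/day
Zinc,1,6,20,6.2,2.8,0.2,13,mg/day
alpha_lactalbumin,2,21,30,0.3,0.2,0,0.9,g/day
Cryptoxanthin,2,21,30,117.3,102.6,0.4,387,mg/day
Gangliosides,2,21,30,3.1,2.6,0.5,12,mg/day
Oligofructose,2,21,30,1.6,1.5,0,5.2,g/day
PFA 18:4,2,21,30,4,5.8,0,26,mg/day
PFA 20:4,2,21,30,0.1,0.1,0,0.3,g/day
PFA 22:5,2,21,30,4.1,6.3,0,42,mg/day
Phosphatidylcholine,2,21,30,0.5,0.7,0,3.5,g/day
Phosphatidylinositol,2,21,30,9.8,11.8,0,47.5,mg/day
Sphingomyelin,2,21,30,7,8.4,0,43.9,mg/day
3'SL,2,21,30,20.6,20.8,0,90.5,mg/day
6'SL,2,21,30,4,4,0.1,18.3,mg/day
Alpha-carotene,3,31,60,276.7,264.1,0,1669.5,mcg/day
alpha_lactalbumin,3,31,60,0.2,0.2,0,0.8,g/day
Alpha tocopherol,3,31,60,6,2.8,0,17.9,mg/day
Gangliosides,3,31,60,3.1,2.5,0.1,13,mg/day
Histidine,3,31,60,0.3,0.2,0,0.9,g/day
Isoleucine,3,31,60,0.5,0.2,0,1.7,g/day
Leucine,3,31,60,1.1,0.7,0,2.9,g/day
Lysine,3,31,60,0.8,0.4,0,2.3,g/day
MFA 20:1,3,31,60,0.1,0.1,0,0.5,g/day
PFA 18:4,3,31,60,6.8,10.1,0,56,mg/day
PFA 20:5,3,31,60,8.3,15.4,0,127,mg/day
PFA 22:5,3,31,60,10.1,8.6,0,37,mg/day
PFA 22:6,3,31,60,32.1,46.2,0,255,mg/day
Phosphatidylcholine,3,31,60,0.6,0.6,0,3.2,g/day
Phosphatidylethanolamine,3,31,60,0.1,0.1,0,0.7,g/day
Phosphorus,3,31,60,894.2,253.4,32.5,1473.6,mg/day
Phosphatidylinositol,3,31,60,16.5,22.1,0,168.3,mg/day
Phosphatidylserine,3,31,60,18.3,34.7,0,293.4,mg/day
Sphingomyelin,3,31,60,9.7,11.4,0.1,76.6,mg/day
Tryptophan,3,31,60,0.1,0.1,0,0.6,g/day
Valine,3,31,60,0.7,0.3,0,2,g/day
3'SL,3,31,60,11.7,15,0,81.6,mg/day
6'SL,3,31,60,2.7,2.9,0,16.5,mg/day
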