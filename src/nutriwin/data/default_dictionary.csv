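name,category,unit,excluded,exclusion_reason
Copper,mineral,mg/day,False,none
Folate,vitamin,mcg/day,False,none
Histidine,amino_acid,g/day,False,none
Iron,mineral,mg/day,False,none
Isoleucine,amino_acid,g/day,False,none
Leucine,amino_acid,g/day,False,none
Magnesium,mineral,mg/day,False,none
Phosphorus,mineral,mg/day,False,none
Potassium,mineral,mg/day,False,none
Selenium,mineral,mcg/day,False,none
Valine,amino_acid,g/day,False,none
Vitamin A,vitamin,mcg/day,False,none
Vitamin B1,vitamin,mg/day,False,none
Vitamin B2,vitamin,mg/day,False,none
Vitamin B6,vitamin,mg/day,False,none
3'SL,hmo,mg/day,False,none
Zinc,mineral,mg/day,False,none
alpha_lactalbumin,protein_fraction,g/day,False,none
Cryptoxanthin,carotenoid,mg/day,False,none
Gangliosides,polar_lipid,mg/day,False,none
Oligofructose,carbohydrate,g/day,False,none
PFA 18:4,fatty_acid,mg/day,False,none
PFA 20:4,fatty_acid,g/day,False,none
PFA 22:5,fatty_acid,mg/day,False,none
Phosphatidylcholine,polar_lipid,g/day,False,none
Phosphatidylinositol,polar_lipid,mg/day,False,none
Sphingomyelin,polar_lipid,mg/day,False,none
6'SL,hmo,mg/day,False,none
Alpha-carotene,carotenoid,mcg/day,False,none
Alpha tocopherol,vitamin,mg/day,False,none
Lysine,amino_acid,g/day,False,none
MFA 20:1,fatty_acid,g/day,False,none
PFA 20:5,fatty_acid,mg/day,False,none
PFA 22:6,fatty_acid,mg/day,False,none
Phosphatidylethanolamine,polar_lipid,g/day,False,none
Phosphatidylserine,polar_lipid,mg/day,False,none
Tryptophan,amino_acid,g/day,False,none
Vitamin B12,vitamin,mcg/day,False,none
Calcium,mineral,mg/day,False,none
Linoleic acid,fatty_acid,g/day,False,none
Arachidonic acid,fatty_acid,mg/day,False,none
alpha-Linolenic acid,fatty_acid,g/day,False,none
Beta-carotene,carotenoid,mcg/day,False,none
Linolelaidic acid,fatty_acid,g/day,False,none
gamma-Linolenic acid,fatty_acid,mg/day,False,none
Octadecenoic acid,fatty_acid,g/day,False,none
Palmitoleic acid,fatty_acid,g/day,False,none
Erucic acid,fatty_acid,mg/day,False,none
Glycine,amino_acid,g/day,False,none
Vitamin C,vitamin,mg/day,False,none
Vitamin D,vitamin,mcg/day,False,none
Vitamin K,vitamin,mcg/day,False,none
Niacin,vitamin,mg/day,False,none
Pantothenic acid,vitamin,mg/day,False,none
Biotin,vitamin,mcg/day,False,none
Free choline,other,mg/day,False,none
Glycerophosphocholine,polar_lipid,mg/day,False,none
Phosphocholine,polar_lipid,mg/day,False,none
Sodium,mineral,mg/day,False,none
Manganese,mineral,mg/day,False,none
Iodine,mineral,mcg/day,False,none
Threonine,amino_acid,g/day,False,none
Lutein,carotenoid,mcg/day,False,none
Methionine,amino_acid,g/day,True,safety_concern
Phenylalanine,amino_acid,g/day,True,safety_concern
Alanine,amino_acid,g/day,True,non_essential_amino_acid
Arginine,amino_acid,g/day,True,non_essential_amino_acid
Asparagine,amino_acid,g/day,True,non_essential_amino_acid
Aspartic acid,amino_acid,g/day,True,non_essential_amino_acid
Cysteine,amino_acid,g/day,True,non_essential_amino_acid
Glutamic acid,amino_acid,g/day,True,non_essential_amino_acid
Glutamine,amino_acid,g/day,True,non_essential_amino_acid
Proline,amino_acid,g/day,True,non_essential_amino_acid
Serine,amino_acid,g/day,True,non_essential_amino_acid
Tyrosine,amino_acid,g/day,True,non_essential_amino_acid
Total phospholipids,polar_lipid,g/day,True,redundant_aggregate
Total fats,other,g/day,True,redundant_aggregate
Total saturated fatty acids,fatty_acid,g/day,True,redundant_aggregate
Total monounsaturated fatty acids,fatty_acid,g/day,True,redundant_aggregate
Total polyunsaturated fatty acids,fatty_acid,g/day,True,redundant_aggregate
Total carbohydrate,carbohydrate,g/day,True,redundant_aggregate
Total protein,other,g/day,True,redundant_aggregate
Total sugars,carbohydrate,g/day,True,redundant_aggregate
Energy,other,kcal/day,True,redundant_aggregate
Total omega-3 fatty acids,fatty_acid,g/day,True,redundant_aggregate
Total omega-6 fatty acids,fatty_acid,g/day,True,redundant_aggregate
Total choline,other,mg/day,True,redundant_aggregate
Total carotenoids,carotenoid,mcg/day,True,redundant_aggregate
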