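# Synthetic illustrative component-level database. These are NOT measured food
# components: names and HSP values are invented around realistic group-level
# means so that component-level screening (mean-of-Ra) can be demonstrated and
# tested. Real analyses should supply a curated components.csv.
name,group,delta_d,delta_p,delta_hb
synthetic_sugar_1,carbohydrates,16.0,13.5,22.0
synthetic_sugar_2,carbohydrates,17.5,16.0,20.5
synthetic_sugar_3,carbohydrates,17.8,17.0,22.4
synthetic_fat_1,fats,16.1,3.2,5.2
synthetic_fat_2,fats,16.5,4.9,6.0
synthetic_fat_3,fats,16.2,3.5,9.0
synthetic_amino_acid_1,amino_acids,17.2,6.5,13.0
synthetic_amino_acid_2,amino_acids,18.9,12.8,19.5
synthetic_vitamin_1,vitamins,17.5,1.2,2.8
synthetic_vitamin_2,vitamins,16.6,4.0,4.5
synthetic_polar_terpenoid_1,polar_essential_oil,17.0,3.4,6.5
synthetic_polar_terpenoid_2,polar_essential_oil,18.3,4.1,9.2
synthetic_nonpolar_terpene_1,nonpolar_essential_oil,16.5,1.1,2.2
synthetic_nonpolar_terpene_2,nonpolar_essential_oil,17.1,2.2,3.7
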