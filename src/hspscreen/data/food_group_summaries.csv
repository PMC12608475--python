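group,n,mean_d,sd_d,mean_p,sd_p,mean_hb,sd_hb,mean_ra,sd_ra
carbohydrates,,17.0,1.4,15.3,2.8,21.6,1.6,22.4,2.2
fats,,16.3,0.3,3.9,0.9,6.7,2.1,8.3,1.1
amino_acids,,18.0,1.0,9.4,3.3,16.2,3.4,15.0,3.7
vitamins,,17.1,0.6,2.4,1.8,3.6,1.1,6.4,0.7
polar_essential_oil,,17.6,0.9,3.7,0.5,7.9,1.8,7.3,1.1
nonpolar_essential_oil,,16.8,0.4,1.6,0.6,2.9,0.9,6.9,0.8
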