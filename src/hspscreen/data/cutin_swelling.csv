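solvent,replicate,percent_swelling,exclude
hexane,1,12,
hexane,2,20,
diethyl ether,1,56,
diethyl ether,2,52,
chloroform,1,175,
chloroform,2,194,
acetone,1,49,
acetone,2,43,
ethyl acetate,1,59,
ethyl acetate,2,51,
isopropanol,1,79,
isopropanol,2,80,
water,1,9,chemical_alteration
water,2,10,chemical_alteration
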