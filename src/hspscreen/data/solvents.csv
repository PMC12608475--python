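name,delta_d,delta_p,delta_hb,source
hexane,14.9,0.0,0.0,Hansen handbook
diethyl ether,14.5,2.9,4.6,Hansen handbook
chloroform,17.8,3.1,5.7,Hansen handbook
acetone,15.5,10.4,7.0,Hansen handbook
ethyl acetate,15.8,5.3,7.2,Hansen handbook
isopropanol,15.8,6.1,16.4,Hansen handbook
water,15.5,16.0,42.3,Hansen handbook
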