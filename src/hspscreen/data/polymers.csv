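name,delta_d,delta_p,delta_hb,ro,ro_solvent,source
cutin,19.7,5.4,2.5,,hexane,five-solvent swelling estimate (this package)
PLA,17.9,9.2,5.9,,,literature HSP for a poly(lactic acid) sample; interaction radius not shipped - supply ro
PHB,,,,,,placeholder: poly(hydroxybutyrate) HSP and Ro are not shipped - supply delta_d/delta_p/delta_hb and ro
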