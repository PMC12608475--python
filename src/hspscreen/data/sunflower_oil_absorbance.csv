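# Documentation-only fixture: visible-light absorbance of sunflower oil stored
# in contact with a cutin film for six months, measured against oil stored
# without cutin as the blank. No computation in this package consumes it; it
# records the experimental confirmation that color-bearing material migrated
# from cutin into the oil.
wavelength_nm,absorbance
400,0.055
550,0.015
700,0.011
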