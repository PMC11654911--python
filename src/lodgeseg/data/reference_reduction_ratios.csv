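layer_id,reduction_ratio_percent
DSCL 01,-15.63
DSCL 02,-10.16
DSCL 03,-37.50
DSCL 04,35.94
DSCL 05,-4.30
DSCL 06,28.13
DSCL 07,-17.58
DSCL 08,-50.00
DSCL 09,7.81
DSCL 10,-25.00
DSCL 11,-23.44
DSCL 12,-36.13
DSCL 13,-4.69
DSCL 14,-49.61
DSCL 15,16.70
DSCL 16,-31.64
DSCL 17,35.94
DSCL 18,-41.02
DSCL 19,34.18
DSCL 20,-45.31
DSCL 21,33.50
DSCL 22,39.06
DSCL 23,-43.46
DSCL 24,35.16
DSCL 25,-34.96
DSCL 26,9.77
DSCL 27,31.25
DSCL 28,31.35
DSCL 29,16.41
DSCL 30,47.27
DSCL 31,-18.36
USCL 01,-34.38
USCL 02,18.36
USCL 03,-32.03
USCL 04,29.69
USCL 05,-37.11
USCL 06,-46.88
USCL 07,-12.50
USCL 08,21.09
USCL 09,12.50
USCL 10,25.00
USCL 11,-5.47
USCL 12,25.00
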