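model,pa_pct,mpa_pct,miou_pct,params_m,flops_g
UConvNeXt,95.2,95.2,91.3,5.83,4.04
AUConvNeXt,95.9,96.0,92.5,5.23,3.87
AAUConvNeXt,96.3,96.3,93.2,4.87,3.69
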