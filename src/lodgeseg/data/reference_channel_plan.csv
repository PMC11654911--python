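layer_id,base,optimized
DSCL 01,32,37
DSCL 02,128,141
DSCL 03,32,44
DSCL 04,64,41
DSCL 05,256,267
DSCL 06,64,46
DSCL 07,256,301
DSCL 08,64,96
DSCL 09,128,118
DSCL 10,512,640
DSCL 11,128,158
DSCL 12,512,697
DSCL 13,128,134
DSCL 14,256,383
DSCL 15,1024,853
DSCL 16,256,337
DSCL 17,1024,656
DSCL 18,256,361
DSCL 19,1024,674
DSCL 20,256,372
DSCL 21,1024,681
DSCL 22,256,156
DSCL 23,1024,1469
DSCL 24,256,166
DSCL 25,1024,1382
DSCL 26,256,231
DSCL 27,256,176
DSCL 28,1024,703
DSCL 29,256,214
DSCL 30,1024,540
DSCL 31,256,303
USCL 01,128,172
USCL 02,512,418
USCL 03,128,169
USCL 04,64,45
USCL 05,256,351
USCL 06,64,94
USCL 07,32,36
USCL 08,128,101
USCL 09,32,28
USCL 10,32,24
USCL 11,128,135
USCL 12,32,24
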