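stratum,n1,n2,n3,n12,n13,n23,n123
Eastern,558,337,126,211,50,64,36
Kigali,885,497,1021,185,128,124,42
Northern,150,25,303,4,20,18,4
Southern,515,291,152,195,42,54,28
Western,357,164,609,126,182,155,100
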