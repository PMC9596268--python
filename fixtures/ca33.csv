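prescription_id,study_id,items
f01,s01,GB34;PC6;RN8;ST36
f02,s02,HT7;RN12;RN4;SP6;ST37
f03,s03,LI11;RN12;SP3;ST36
f04,s04,HT7;RN12;RN4;SP6;ST21
f05,s05,BL20;HT7;LI4;RN12;SP9
f06,s06,BL17;GB20;RN8;ST36
f07,s07,BL13;BL23;RN13;ST36;ST40
f08,s08,DU20;PC6;RN12;ST25;ST36
f09,s09,DU14;PC6;RN6;ST36
f10,s10,DU20;RN12;SJ6;SP6
f11,s11,DU20;PC6;RN12;ST19;ST36
f12,s12,DU20;PC6;RN12;ST36
f13,s13,PC6;RN12;RN4;SP6;ST36
f14,s14,DU20;PC6;RN12;ST36
f15,s15,BL21;LR3;RN12;ST25;ST36
f16,s16,HT7;RN12;RN4;SP6;ST37
f17,s17,DU20;HT7;PC6;RN12
f18,s18,DU20;HT7;PC6;RN12
f19,s19,PC6;RN12;RN4;SP6;ST36
f20,s20,DU26;PC6;RN6;ST36
f21,s21,RN12;RN4;SP10;ST36
f22,s22,HT7;RN12;RN4;SP6
f23,s23,BL20;LI10;SJ6;ST36
f24,s24,HT7;RN12;RN4;SP6
f25,s25,LI11;SP6;SP9;ST36
f26,s26,DU20;RN12;RN4;SP6;ST36
f27,s27,BL23;RN10;SP6;ST36;ST39
f28,s01,PC6;RN4;SP6;ST36
f29,s02,HT7;PC6;RN12;RN4;SP6;ST36
f30,s03,BL18;KI3;SJ5;ST36
f31,s04,BL13;BL21;LI4;ST19;ST36
f32,s05,PC5;RN12;RN4;ST36;ST39
f33,s06,DU20;RN12;RN4;SP6;ST36
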