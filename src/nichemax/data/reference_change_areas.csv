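scenario,kind,direction,class_low,class_high,contraction_1e3km2,expansion_1e3km2,inconsistent_total
LGM,class,past-to-current,0.03,0.1,28,242,False
LGM,class,past-to-current,0.1,0.2,17,431,False
LGM,class,past-to-current,0.2,0.4,16,517,False
LGM,class,past-to-current,0.4,0.6,8,342,False
LGM,class,past-to-current,0.6,1.0,1,309,False
LGM,printed_total,past-to-current,0.03,1.0,70,2441,True
MH,class,past-to-current,0.03,0.1,120,750,False
MH,class,past-to-current,0.1,0.2,65,382,False
MH,class,past-to-current,0.2,0.4,43,490,False
MH,class,past-to-current,0.4,0.6,20,329,False
MH,class,past-to-current,0.6,1.0,18,292,False
MH,printed_total,past-to-current,0.03,1.0,266,2243,False
RCP45-2050,class,current-to-future,0.03,0.1,196,675,False
RCP45-2050,class,current-to-future,0.1,0.2,157,290,False
RCP45-2050,class,current-to-future,0.2,0.4,291,242,False
RCP45-2050,class,current-to-future,0.4,0.6,250,99,False
RCP45-2050,class,current-to-future,0.6,1.0,260,50,False
RCP45-2050,printed_total,current-to-future,0.03,1.0,1154,1356,False
RCP45-2070,class,current-to-future,0.03,0.1,206,664,False
RCP45-2070,class,current-to-future,0.1,0.2,171,277,False
RCP45-2070,class,current-to-future,0.2,0.4,305,228,False
RCP45-2070,class,current-to-future,0.4,0.6,259,91,False
RCP45-2070,class,current-to-future,0.6,1.0,267,43,False
RCP45-2070,printed_total,current-to-future,0.03,1.0,1208,1303,False
RCP85-2050,class,current-to-future,0.03,0.1,228,642,False
RCP85-2050,class,current-to-future,0.1,0.2,175,273,False
RCP85-2050,class,current-to-future,0.2,0.4,332,201,False
RCP85-2050,class,current-to-future,0.4,0.6,280,70,False
RCP85-2050,class,current-to-future,0.6,1.0,280,29,False
RCP85-2050,printed_total,current-to-future,0.03,1.0,1295,1215,False
RCP85-2070,class,current-to-future,0.03,0.1,264,606,False
RCP85-2070,class,current-to-future,0.1,0.2,202,246,False
RCP85-2070,class,current-to-future,0.2,0.4,365,168,False
RCP85-2070,class,current-to-future,0.4,0.6,296,53,False
RCP85-2070,class,current-to-future,0.6,1.0,286,24,False
RCP85-2070,printed_total,current-to-future,0.03,1.0,1413,1097,False
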