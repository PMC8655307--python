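segment,mass_pct,ls_pct,lv_pct,lower_marker,upper_marker
foot,1,32,0,mtp,ankle
leg,9,68,0,ankle,hip
lower_trunk,53,18,33,hip,mid_trunk
upper_trunk,29,40,10,mid_trunk,scapula
head,8,33,-7,tmj,nose
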