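"","logFC","t","P.Value","adj.P.Val"
"g0"," 1.9522191262128"," 4.019927115055","0.000108048472008","0.000824369927377"
"g1","-1.9204226995945","-3.954453257224","0.000137394987896","0.000824369927377"
"g2"," 0.6413593218289"," 1.320660008754","0.189406469692600","0.336143701766720"
"g3"," 0.1177802607505"," 0.242528135009","0.808830936917620","0.849514159537947"
"g4","-0.6317312918810","-1.300834376409","0.196083826030587","0.336143701766720"
"g5","-0.0973746218233","-0.200509705765","0.841459068207701","0.849514159537947"
"g6"," 0.0923649410168"," 0.190193982780","0.849514159537947","0.849514159537947"
"g7","-0.3723544228366","-0.766736490117","0.444910996569529","0.667366494854293"
"g8","-1.0698987178910","-2.203090221104","0.029712376661168","0.089137129983505"
"g9","-0.6318880995624","-1.301157268159","0.195973691373035","0.336143701766720"
"g10"," 0.2698440478054"," 0.555651458406","0.579598385243028","0.772797846990705"
"g11","-1.0998023711750","-2.264666560083","0.025529486194311","0.089137129983505"
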