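pool,ns_span_m,ew_span_m,area_m2,max_depth_m,volume_m3,clay_bottom_pct,soil_type
1,13.10,21.50,281.65,0.47,34.66,83.60,ReB
2,13.30,13.70,182.21,0.24,11.45,78.40,CkB
3,19.10,19.90,380.09,0.31,30.85,75.20,CkB
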