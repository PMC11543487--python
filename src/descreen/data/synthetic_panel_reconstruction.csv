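# SYNTHETIC reconstruction: FDH activity and FDH half-life values for the
# buffered choline chloride:glycerol dilution series that the study narrative
# describes only qualitatively ("little or no activity at <=50% aqueous phase",
# "10% dilutions destabilize faster", "90% dilutions stabilize like the buffer").
# These fills exist solely so the radar/trade-off panel has a complete value for
# every axis; they respect the qualitative ordering but are NOT measured data.
system_id,fdh_half_life_d,relative_activity_pct
ChCl:Gly_10%B,1.0,0.0
ChCl:Gly_30%B,20.0,5.0
ChCl:Gly_50%B,10.0,10.0
ChCl:Gly_80%B,,30.0
ChCl:Gly_90%B,2.1,
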