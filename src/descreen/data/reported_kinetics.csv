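# Half-lives and relative activities for the glycerol-DES screening systems as
# reported in the study narrative. Empty cells were not printed.
# relative_activity_pct for B:Gly_30%B was printed as "less than 2%" and is stored as 2.0.
system_id,fdh_half_life_d,nadh_half_life_d,relative_activity_pct
buffer,2.1,4.6,100.0
ChCl:Gly_80%B,29.9,,
ChCl:Gly_90%B,,2.9,44.5
ChCl:Gly_10%B,,44.2,
ChCl:Gly_90%W,,,92.0
B:Gly_80%B,65.6,,51.7
B:Gly_30%B,40.1,12.1,2.0
B:Gly_90%B,6.0,,71.2
B:Gly_10%B,,17.5,
B:Gly_30%W,,65.7,
B:Gly_90%W,,0.8,
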