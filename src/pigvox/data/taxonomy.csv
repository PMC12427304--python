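behavior,level1,valence
grunting,vocalization,positive_neutral
playing_behavior,vocalization,positive_neutral
conflict_over_resources,vocalization,negative
fight,vocalization,negative
oral_manipulation,vocalization,negative
aversive_physical_contact,vocalization,negative
alert,vocalization,alert
coughing,other,other
sneezing,other,other
ear_shaking,other,other
snoring,other,other
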