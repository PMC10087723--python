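study,d,se
Detection of erotic stimuli,0.25,0.101550
Avoidance of negative stimuli,0.2,0.082462
Retroactive priming I,0.26,0.103236
Retroactive priming II,0.23,0.101824
Retroactive habituation I,0.22,0.101203
Retroactive habituation II,0.15,0.082108
Induction of boredom,0.09,0.070854
Facilitation of recall I,0.19,0.100898
Facilitation of recall II,0.42,0.147526
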