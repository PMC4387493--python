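segment,pref,min,max,ce
head,0.0056,0.0056,0.0056,0.0119
neck,0.0177,0.0152,0.0199,0.0425
trunk,1.0786,0.8724,1.3686,2.9174
left upper arm,0.0098,0.0098,0.0098,0.0208
left forearm,0.0046,0.0046,0.0046,0.0099
left hand,0.0021,0.0021,0.0021,0.0046
left thigh,0.0159,0.0159,0.0159,0.0339
left shank,0.0084,0.0084,0.0084,0.0178
left foot,0.0018,0.0018,0.0018,0.0038
right upper arm,0.0084,0.0084,0.0084,0.0180
right forearm,0.0042,0.0042,0.0042,0.0091
right hand,0.0020,0.0020,0.0020,0.0043
right thigh,0.0166,0.0166,0.0166,0.0354
right shank,0.0091,0.0091,0.0091,0.0194
right foot,0.0014,0.0014,0.0014,0.0031
tail,0.0936,0.0781,0.1061,0.2262
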