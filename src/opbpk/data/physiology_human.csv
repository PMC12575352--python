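# Reference whole-body physiology, adult human male, 70 kg, cardiac output 336 L/h.
# Compendium-style values (Brown et al. 1997, Toxicol Ind Health 13:407; ICRP 89),
# rounded; bone mineral and GI contents are not modelled, so compartment volumes
# sum to ~95% of body weight at density 1 kg/L. rest_of_body closes the flow
# balance: its flow = cardiac output - sum of named tissue flows.
# Blood pools carry no perfusion flow of their own (flow set to 0).
compartment,volume_L,flow_L_per_h
lung,0.53,336.0
adipose,14.5,16.8
muscle,28.0,57.12
liver,1.82,63.84
spleen,0.18,10.08
heart,0.33,13.44
brain,1.4,40.32
kidney,0.31,58.8
skin,2.6,19.488
reproductive_organs,0.035,1.68
red_marrow,1.1,10.08
yellow_marrow,2.4,3.36
rest_of_body,7.77,40.992
arterial_blood,1.84,0
venous_blood,3.69,0
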