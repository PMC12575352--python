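# Reference whole-body physiology, male Sprague-Dawley rat, 0.25 kg,
# cardiac output 5.0 L/h. Compendium-style values (Brown et al. 1997), rounded;
# compartment volumes sum to ~95% of body weight at density 1 kg/L.
# rest_of_body closes the flow balance (cardiac output - named tissue flows).
# Blood pools carry no perfusion flow of their own (flow set to 0).
compartment,volume_L,flow_L_per_h
lung,0.00125,5.0
adipose,0.019,0.35
muscle,0.101,1.39
liver,0.00915,0.915
spleen,0.0005,0.05
heart,0.000825,0.245
brain,0.001425,0.10
kidney,0.001825,0.705
skin,0.0475,0.29
reproductive_organs,0.0025,0.025
red_marrow,0.00375,0.12
yellow_marrow,0.00375,0.04
rest_of_body,0.026525,0.77
arterial_blood,0.0062,0
venous_blood,0.0123,0
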