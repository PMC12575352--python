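# Tissue/blood partition coefficients, fentanyl, human, interspecies
# extrapolation from the rat report values (literature values shipped as a
# fixture; uniform scaling factor ~0.837 relative to the rat report row).
tissue,kp
lung,12.56
adipose,25.11
muscle,2.93
liver,3.6
spleen,25.95
heart,4.27
brain,3.35
kidney,10.04
skin,3.49
reproductive_organs,7.35
red_marrow,2.64
yellow_marrow,7.42
rest_of_body,4.60
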