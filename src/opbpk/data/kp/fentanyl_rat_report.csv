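# Tissue/blood partition coefficients, fentanyl, rat, literature report values
# (experimentally derived; shipped as a fixture).
tissue,kp
lung,15
adipose,30
muscle,3.5
liver,4.3
spleen,31
heart,5.1
brain,4
kidney,12
skin,4.17
reproductive_organs,8.78
red_marrow,3.15
yellow_marrow,8.87
rest_of_body,5.49
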