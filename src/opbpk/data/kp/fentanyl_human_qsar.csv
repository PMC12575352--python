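# Tissue/blood partition coefficients, fentanyl, human, structure-based QSAR
# prediction (literature values shipped as a fixture).
tissue,kp
lung,3.29
adipose,7.74
muscle,3.10
liver,6.46
spleen,4.28
heart,3.79
brain,5.37
kidney,5.56
skin,3.36
reproductive_organs,5.56
red_marrow,5.99
yellow_marrow,7.74
rest_of_body,4.28
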