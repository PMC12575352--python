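# Tissue/blood partition coefficients, beta-hydroxythiofentanyl, rat,
# structure-based QSAR prediction (literature values shipped as a fixture).
tissue,kp
lung,3.72
adipose,1.62
muscle,1.98
liver,4.91
spleen,3.42
heart,2.66
brain,1.73
kidney,5.03
skin,1.92
reproductive_organs,5.03
red_marrow,2.03
yellow_marrow,1.62
rest_of_body,3.42
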