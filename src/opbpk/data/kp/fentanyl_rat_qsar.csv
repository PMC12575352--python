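# Tissue/blood partition coefficients, fentanyl, rat, structure-based QSAR
# prediction (literature values shipped as a fixture).
tissue,kp
lung,13.90
adipose,17.63
muscle,5.96
liver,15.02
spleen,9.92
heart,8.46
brain,32.48
kidney,15.88
skin,7.88
reproductive_organs,15.88
red_marrow,6.06
yellow_marrow,17.63
rest_of_body,9.92
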