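# Fractional tissue composition used by the tissue-composition (Rodgers-Rowland
# style) partition-coefficient predictor. f_ew/f_iw: extracellular/intracellular
# water fractions; f_nl/f_np: neutral lipid / neutral phospholipid fractions;
# ap_mg_per_g: acidic phospholipid concentration; pr_ratio: tissue-to-plasma
# binding-protein concentration ratio (used for neutrals/acids/weak bases).
# Values adapted from published rat compendia (Rodgers & Rowland 2005, 2006);
# the same table is applied to both species, a standard simplification.
# Stand-ins (no published row exists): reproductive_organs ~ thymus,
# red_marrow ~ spleen, yellow_marrow ~ adipose, rest_of_body ~ lean-tissue mean.
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_per_g,pr_ratio
lung,0.336,0.446,0.022,0.0128,3.91,0.212
adipose,0.135,0.017,0.853,0.0016,0.40,0.049
muscle,0.118,0.630,0.010,0.0072,1.53,0.059
liver,0.161,0.573,0.014,0.0240,4.56,0.086
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097
heart,0.320,0.456,0.014,0.0111,2.25,0.157
brain,0.162,0.620,0.039,0.0015,0.40,0.048
kidney,0.273,0.483,0.012,0.0240,5.03,0.130
skin,0.382,0.291,0.060,0.0044,1.32,0.277
reproductive_organs,0.150,0.626,0.017,0.0092,1.30,0.075
red_marrow,0.207,0.579,0.0077,0.0113,3.18,0.097
yellow_marrow,0.135,0.017,0.853,0.0016,0.40,0.049
rest_of_body,0.160,0.560,0.030,0.0090,2.00,0.100
blood_cells,0.0,0.603,0.0017,0.0029,0.50,0.0
plasma,0.0,0.0,0.0023,0.0013,0.0,1.0
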