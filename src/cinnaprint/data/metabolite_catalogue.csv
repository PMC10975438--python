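name,formula,mol_weight,center_ppm,window_lo,window_hi,n_protons,multiplicity,secondary
Cinnamaldehyde,C9H8O,132.16,9.69,9.64,9.74,1,d (CHO),7.40:1;7.20:2
Coumarin,C9H6O2,146.14,7.91,7.86,7.96,1,d (H-4),6.25:1;7.35:2
Methoxy cinnamaldehyde,C10H10O2,162.19,3.77,3.72,3.82,3,s (OCH3),9.40:1;7.50:2
Cinnamic acid,C9H8O2,148.16,6.50,6.45,6.55,1,d (H-alpha),7.65:1
Benzoic acid,C7H6O2,122.12,8.05,8.00,8.10,2,m (H-2/6),7.55:3
Methyl salicylate,C8H8O3,152.15,3.97,3.92,4.02,3,s (OCH3),7.10:1
Quinic acid,C7H12O6,192.17,4.29,4.24,4.34,1,m (H-5),2.05:2;1.95:2
Eugenol,C10H12O2,164.20,5.95,5.90,6.00,1,m (CH=),7.25:2;5.50:2
alpha-Glucose,C6H12O6,180.16,5.23,5.18,5.28,1,d (H-1),2.95:2
beta-Glucose,C6H12O6,180.16,4.63,4.58,4.68,1,d (H-1),3.05:2
Fructose,C6H12O6,180.16,4.13,4.08,4.18,1,m (H-4),2.85:2
Formic acid,CH2O2,46.03,8.45,8.40,8.50,1,s (HCOOH),
Choline,C5H14NO,104.17,4.45,4.40,4.50,2,m (OCH2),3.52:2;3.20:9
Shikimic acid,C7H10O5,174.15,6.83,6.78,6.88,1,m (H-2),2.20:2
Succinic acid,C4H6O4,118.09,2.55,2.50,2.60,4,s (CH2CH2),
Alanine,C3H7NO2,89.09,1.48,1.43,1.53,3,d (CH3),
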