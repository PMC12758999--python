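organ,n_osl,ct_dose_mgy,ct_u_mgy,cbct_dose_mgy,cbct_u_mgy
temporal_parietal_bones,4,4.81,0.62,4.786,0.77
eyes,2,3.69,0.58,4.227,0.68
brain,10,4.92,0.77,5.720,0.92
brainstem,2,5.02,0.81,5.878,0.95
mandible,3,5.53,0.06,6.132,0.99
thyroid,4,7.80,1.18,3.61,0.58
sternum,1,5.59,0.90,4.93,0.79
heart,5,6.82,0.98,4.373,0.7
lungs,12,5.69,0.89,5.651,0.91
stomach,10,4.19,0.71,5.892,0.95
liver,18,5.67,0.75,6.129,0.99
spleen,4,7.39,1.04,6.024,0.97
kidneys,6,5.40,0.99,4.763,0.77
abdominal_cavity,10,6.63,1.07,6.312,1.022
vertebrae,6,4.31,0.63,3.221,0.51
bony_pelvis,14,4.40,0.67,6.131,0.99
femoral_heads,2,5.68,0.83,5.817,0.94
bladder,6,5.37,0.79,5.783,1.26
prostate,1,5.32,0.88,4.935,0.79
testicles,2,4.19,0.81,4.610,0.74
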