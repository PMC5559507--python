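# channel -> region-of-interest map for the default 32-channel montage.
# 22 regions (11 per hemisphere); midline channels (Fz, Cz, Pz, Oz) are
# deliberately unmapped and excluded from ROI aggregation.
channel	roi
Fp1	frontopolar_L
AF3	frontal_L
F3	frontal_L
F7	frontal_lateral_L
FC1	frontocentral_L
FC5	frontocentral_L
C3	central_L
T7	temporal_L
CP1	centroparietal_L
CP5	centroparietal_L
P3	parietal_L
P7	parietal_lateral_L
PO3	parietooccipital_L
O1	occipital_L
Fp2	frontopolar_R
AF4	frontal_R
F4	frontal_R
F8	frontal_lateral_R
FC2	frontocentral_R
FC6	frontocentral_R
C4	central_R
T8	temporal_R
CP2	centroparietal_R
CP6	centroparietal_R
P4	parietal_R
P8	parietal_lateral_R
PO4	parietooccipital_R
O2	occipital_R
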