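# Default 10-10 electrode -> AAL-90 region map (0-based region indices).
#
# Assigning scalp electrode positions to underlying AAL regions is a
# clinical judgement call; this default encodes common cranio-cortical
# correlates (e.g. F7 over the left inferior frontal gyrus) and is a
# convention, not ground truth.  Override with --site-map for vetted
# assignments.
#
# Index reference (AAL-90 order): 0/1 Precentral L/R, 2/3 Frontal_Sup L/R,
# 6/7 Frontal_Mid L/R, 12/13 Frontal_Inf_Tri L/R, 14/15 Frontal_Inf_Orb L/R,
# 56/57 Postcentral L/R, 60/61 Parietal_Inf L/R, 62/63 SupraMarginal L/R.
F7: [12, 14]
F8: [13, 15]
F4: [7, 3]
F3: [6, 2]
CP6: [63]
Between C3-FC1: [0]
Between C3-F3: [6, 0]
Between F4-Fz: [3]
Between C4-P4: [57, 61]
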