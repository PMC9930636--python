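# Resting-state network membership over the 116-region AAL atlas
# (standard AAL ordering: 1-90 cerebral regions in left/right pairs,
# 91-116 cerebellum and vermis).
#
# REFERENCE RECONSTRUCTION: these memberships follow the common usage of
# the AAL parcellation in the resting-state literature (mPFC/PCC/precuneus/
# angular/hippocampal DMN; dorsolateral-prefrontal + parietal CEN;
# pre/postcentral + SMA sensorimotor network; insular-cingulate salience;
# occipital visual). They are a convention, not a measurement — edit this
# file to match your own atlas-to-network assignment.
#
# Indices are 1-based AAL region numbers.
DMN: [23, 24, 25, 26, 31, 32, 35, 36, 37, 38, 65, 66, 67, 68, 85, 86]
CEN: [7, 8, 11, 12, 13, 14, 59, 60, 61, 62]
SM: [1, 2, 19, 20, 57, 58, 69, 70]
salience: [29, 30, 31, 32, 33, 34]
visual: [43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54]
whole_brain: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
              19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34,
              35, 36, 37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50,
              51, 52, 53, 54, 55, 56, 57, 58, 59, 60, 61, 62, 63, 64, 65, 66,
              67, 68, 69, 70, 71, 72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82,
              83, 84, 85, 86, 87, 88, 89, 90, 91, 92, 93, 94, 95, 96, 97, 98,
              99, 100, 101, 102, 103, 104, 105, 106, 107, 108, 109, 110, 111,
              112, 113, 114, 115, 116]
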