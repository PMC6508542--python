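# Default leaf subregion polygons over the 15-landmark scheme (1-based indices).
#
# Landmark semantics assumed by this spec:
#   1  petiolar junction              9  distal lobe tip (right)
#   2  midvein base (left)           10  proximal lobe tip (left)
#   3  midvein base (right)          11  proximal lobe tip (right)
#   4  proximal vein base (left)     12  proximal sinus (left)
#   5  proximal vein base (right)    13  proximal sinus (right)
#   6  distal vein branch point      14  distal sinus (left)
#   7  apex (midvein tip)            15  distal sinus (right)
#   8  distal lobe tip (left)
#
# The four subregions tile the whole-leaf polygon exactly: every internal edge
# is shared by exactly two polygons, so the shoelace subareas sum to the total
# area on any configuration (up to sign consistency when polygons are simple).
total: [1, 11, 13, 9, 15, 7, 14, 8, 12, 10]
subregions:
  proximal_vein: [1, 11, 5, 4, 10]
  proximal_blade: [4, 5, 11, 13, 3, 2, 12, 10]
  midvein: [2, 3, 6]
  distal_blade: [3, 13, 9, 15, 7, 14, 8, 12, 2, 6]
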