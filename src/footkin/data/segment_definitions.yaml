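# Segment-fixed frame definitions for the four-segment foot model plus the
# shank reference segment.  Each segment is built from three points:
#   z (long axis)  = unit(long_axis - origin)
#   x              = unit((plane - origin) x z)
#   y              = z x x
# followed by intrinsic attitude offsets about the segment's own axes in
# order X, Y, Z (degrees; see docs/methods.md for the rotation sense).
# Values are for the right side; for the left side the RZ offset changes
# sign (mirror symmetry).
#
# anatomical_axes maps the segment's local axes onto anatomical directions
# (used when resolving joint moments): ml = medio-lateral, ap =
# antero-posterior, vert = vertical; a leading '-' flips the local axis.
segments:
  - name: shank
    parent: Global
    origin: V_Knee_JC
    long_axis: V_Ankle_JC
    plane: KNE_LAT
    rx: 0
    ry: 0
    rz: -90
    anatomical_axes: {ml: x, ap: y, vert: -z}
  - name: hindfoot
    parent: shank
    origin: BC
    long_axis: V_Ankle_JC
    plane: TC
    rx: 0
    ry: 0
    rz: 0
    anatomical_axes: {ml: x, ap: z, vert: y}
  - name: midfoot
    parent: hindfoot
    origin: V_Ankle_JC
    long_axis: TH
    plane: V_MidNC
    rx: 0
    ry: 0
    rz: 180
    anatomical_axes: {ml: x, ap: z, vert: y}
  - name: forefoot
    parent: midfoot
    origin: V_MidNC
    long_axis: V_1_5MTH
    plane: NV
    rx: 0
    ry: 0
    rz: 90
    anatomical_axes: {ml: x, ap: z, vert: y}
  - name: hallux
    parent: forefoot
    origin: 1MTH
    long_axis: HLX
    plane: 23T
    rx: 0
    ry: 0
    rz: -90
    anatomical_axes: {ml: x, ap: z, vert: y}
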