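# 20-unit lower-limb muscle set (right leg).
#
# Path points are segment-local mm for a 1.75 m subject and are scaled
# linearly with subject height at load time.  fmax is the maximum
# isometric force (N); l_opt the optimal fiber length (mm).  The values
# are literature-style defaults chosen for plausible gait moment
# capacity; they are editable configuration, not measured subject data.
#
# Wrap surfaces are cylinders {segment, point, axis, radius} (mm).
reference_height: 1.75
muscles:
  - name: gluteus_maximus_1
    fmax: 900.0
    l_opt: 147.0
    path: [[pelvis, -90, 35, 115], [thigh, -6, -50, 28]]
  - name: gluteus_maximus_2
    fmax: 750.0
    l_opt: 147.0
    path: [[pelvis, -115, -5, 92], [thigh, -10, -100, 12]]
  - name: gluteus_maximus_3
    fmax: 550.0
    l_opt: 144.0
    path: [[pelvis, -120, -45, 70], [thigh, -8, -145, 2]]
  - name: iliopsoas
    fmax: 1900.0
    l_opt: 100.0
    path: [[pelvis, -20, 40, 60], [pelvis, 40, -52, 82], [thigh, 6, -55, 12]]
  - name: pectineus
    fmax: 400.0
    l_opt: 100.0
    path: [[pelvis, 15, -45, 55], [thigh, -5, -95, -2]]
  - name: rectus_femoris
    fmax: 1100.0
    l_opt: 84.0
    path: [[pelvis, 25, -35, 85], [thigh, 45, -400, 3], [shank, 38, -48, 5]]
  - name: vastus_medialis
    fmax: 1300.0
    l_opt: 89.0
    path: [[thigh, 12, -150, -14], [thigh, 42, -400, -8], [shank, 36, -48, 0]]
  - name: vastus_intermedius
    fmax: 1250.0
    l_opt: 87.0
    path: [[thigh, 16, -160, 2], [thigh, 45, -400, 3], [shank, 38, -48, 6]]
  - name: vastus_lateralis
    fmax: 1850.0
    l_opt: 84.0
    path: [[thigh, 12, -150, 24], [thigh, 42, -400, 14], [shank, 36, -48, 12]]
  - name: semimembranosus
    fmax: 1300.0
    l_opt: 80.0
    path: [[pelvis, -70, -70, 48], [shank, -18, -32, -30]]
  - name: semitendinosus
    fmax: 400.0
    l_opt: 201.0
    path: [[pelvis, -72, -75, 44], [shank, -10, -62, -32]]
  - name: biceps_femoris_long
    fmax: 900.0
    l_opt: 109.0
    path: [[pelvis, -68, -70, 56], [shank, -26, -36, 26]]
  - name: biceps_femoris_short
    fmax: 400.0
    l_opt: 173.0
    path: [[thigh, -16, -250, 14], [shank, -26, -36, 24]]
  - name: gastrocnemius_medial
    fmax: 1150.0
    l_opt: 60.0
    path: [[thigh, -32, -395, -14], [foot, -48, -40, -6]]
    wrap: {segment: thigh, point: [-12, -425, 0], axis: [0, 0, 1], radius: 22}
  - name: gastrocnemius_lateral
    fmax: 500.0
    l_opt: 65.0
    path: [[thigh, -32, -395, 18], [foot, -48, -40, 6]]
    wrap: {segment: thigh, point: [-12, -425, 0], axis: [0, 0, 1], radius: 22}
  - name: soleus
    fmax: 2850.0
    l_opt: 50.0
    path: [[shank, -24, -120, 10], [foot, -48, -40, 0]]
  - name: tibialis_anterior
    fmax: 900.0
    l_opt: 70.0
    path: [[shank, 24, -120, 10], [shank, 28, -410, -8], [foot, 55, -45, -18]]
  - name: tibialis_posterior
    fmax: 1250.0
    l_opt: 31.0
    path: [[shank, -14, -120, -4], [shank, -16, -405, -26], [foot, 18, -55, -26]]
  - name: extensor_hallucis_longus
    fmax: 150.0
    l_opt: 75.0
    path: [[shank, 20, -200, 2], [shank, 30, -412, -6], [foot, 120, -55, -20]]
  - name: extensor_digitorum_longus
    fmax: 350.0
    l_opt: 60.0
    path: [[shank, 22, -200, 16], [shank, 30, -412, 10], [foot, 110, -55, 14]]
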