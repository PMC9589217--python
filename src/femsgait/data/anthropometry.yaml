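# Segment inertial and dimensional parameters for the right-lower-limb
# linkage, expressed as standard anthropometric fractions of subject
# height H (m) and mass M (kg).  Lengths become mm after scaling.
#
# mass_frac:      segment mass / M
# length_frac:    segment longitudinal length / H
# com_frac:       COM distance from the proximal joint / segment length
# gyration_frac:  transverse radius of gyration about the COM / segment length
segments:
  pelvis:
    mass_frac: 0.142
    length_frac: 0.050      # vertical drop from pelvis origin to hip centre line
    com_frac: 0.5
    gyration_frac: 0.30
  thigh:
    mass_frac: 0.100
    length_frac: 0.245
    com_frac: 0.433
    gyration_frac: 0.323
  shank:
    mass_frac: 0.0465
    length_frac: 0.246
    com_frac: 0.433
    gyration_frac: 0.302
  foot:
    mass_frac: 0.0145
    length_frac: 0.152      # heel-to-toe length
    com_frac: 0.5
    gyration_frac: 0.475
hip_half_spacing_frac: 0.0485   # right hip centre lateral offset / H
hip_drop_frac: 0.034            # pelvis origin to hip centre vertical drop / H
ankle_height_frac: 0.039        # ankle centre above the sole / H
heel_frac: 0.039                # ankle centre anterior of the heel / H
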