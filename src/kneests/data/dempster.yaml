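# Dempster body-segment parameters (as tabulated by Winter).
# mass_fraction: segment mass / total body mass
# com_fraction: COM distance from the proximal end / segment length
# gyration_fractions: radius of gyration about the COM / segment length,
#   per segment axis (x = mediolateral, y = anterior, z = longitudinal)
thigh:
  mass_fraction: 0.100
  com_fraction: 0.433
  gyration_fractions: {x: 0.323, y: 0.323, z: 0.120}
shank:
  mass_fraction: 0.0465
  com_fraction: 0.433
  gyration_fractions: {x: 0.302, y: 0.302, z: 0.100}
foot:
  mass_fraction: 0.0145
  com_fraction: 0.500
  gyration_fractions: {x: 0.475, y: 0.475, z: 0.150}
# head + arms + trunk lumped with the pelvis; COM fraction is along the
# trunk axis above the hip-centre level
hat:
  mass_fraction: 0.678
  com_fraction: 0.626
  gyration_fractions: {x: 0.496, y: 0.496, z: 0.300}
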