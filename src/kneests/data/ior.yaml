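# IOR-style anatomical lower-limb marker set.
# "{S}" expands to R / L (side prefix); segments likewise get a _r / _l suffix.
# Static trial: 26 markers.  Dynamic trials: 20 (static_only removed).
name: IOR
pelvis:
  markers: [RASI, LASI, RPSI, LPSI]
  tracking: [RASI, LASI, RPSI, LPSI]
per_side:
  thigh:
    markers: ["{S}GT", "{S}LE", "{S}ME"]
    # two physical targets; pose made determinate by augmenting with the
    # pelvis-reconstructed hip joint centre (see model_calibration docs)
    tracking: ["{S}GT", "{S}LE"]
    augment_hip_center: true
  shank:
    markers: ["{S}FH", "{S}TT", "{S}LM", "{S}MM"]
    tracking: ["{S}FH", "{S}TT", "{S}LM"]
  foot:
    markers: ["{S}CA", "{S}FM", "{S}SM", "{S}VM"]
    tracking: ["{S}CA", "{S}SM", "{S}VM"]
static_only: ["{S}ME", "{S}MM", "{S}FM"]
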