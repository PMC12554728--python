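# CAST-style marker set: anatomical calibration markers + rigid four-marker
# clusters on the lateral mid-thigh and mid-shank (131 x 80 mm plates).
# Static trial: 36 markers.  Dynamic trials: 28 (static_only removed).
name: CAST
pelvis:
  markers: [RASI, LASI, RPSI, LPSI]
  tracking: [RASI, LASI, RPSI, LPSI]
per_side:
  thigh:
    markers: ["{S}LE", "{S}ME", "{S}TH1", "{S}TH2", "{S}TH3", "{S}TH4"]
    tracking: ["{S}TH1", "{S}TH2", "{S}TH3", "{S}TH4"]
  shank:
    markers: ["{S}LM", "{S}MM", "{S}SK1", "{S}SK2", "{S}SK3", "{S}SK4"]
    tracking: ["{S}SK1", "{S}SK2", "{S}SK3", "{S}SK4"]
  foot:
    markers: ["{S}CA", "{S}FM", "{S}SM", "{S}VM"]
    tracking: ["{S}CA", "{S}FM", "{S}SM", "{S}VM"]
static_only: ["{S}LE", "{S}ME", "{S}LM", "{S}MM"]
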