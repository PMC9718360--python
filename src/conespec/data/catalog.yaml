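# Default eight-class cone catalog for the zebrafish cone-PIII spectral model.
#
# wlmax_nm: absorbance peaks of the eight cone opsin classes (literature
#   constants; not fitted).
# delta_log_k: log10 semi-saturation irradiance of each cone class relative
#   to the UV cone (delta of UV is 0 by definition; R1 and R2 share one
#   value so a single long-wavelength semi-saturation exists).
#   *** The delta values below are illustrative placeholders. ***
#   They produce realistic-looking synthetic data but are NOT calibrated
#   measurements; substitute literature values for your preparation before
#   analysing real recordings.
# templates: two absorbance shapes (UV pigments are narrower than the
#   blue/green/red family); each is translated along the reciprocal
#   wavelength axis to the cone's peak.  To use your own 8th-order
#   polynomial template, replace a template entry with e.g.
#     kind: polynomial
#     coefficients: [c0, c1, ..., c8]   # log10 absorbance in u
#     reciprocal_scale: 1000.0          # u = scale * (1/wl - 1/wlmax), nm^-1 -> um^-1

floor: 1.0e-6
valid_domain_nm: [300.0, 750.0]

templates:
  uv:
    kind: govardovskii_a1
    anchor_nm: 360.0
  rgb:
    kind: govardovskii_a1
    anchor_nm: 500.0

cones:
  - {label: UV, wlmax_nm: 358.0, delta_log_k: 0.00, template: uv}
  - {label: B1, wlmax_nm: 415.0, delta_log_k: 0.08, template: rgb}
  - {label: B2, wlmax_nm: 440.0, delta_log_k: 0.15, template: rgb}
  - {label: G1, wlmax_nm: 460.0, delta_log_k: 0.25, template: rgb}
  - {label: G3, wlmax_nm: 480.0, delta_log_k: 0.30, template: rgb}
  - {label: G4, wlmax_nm: 500.0, delta_log_k: 0.35, template: rgb}
  - {label: R2, wlmax_nm: 556.0, delta_log_k: 0.45, template: rgb}
  - {label: R1, wlmax_nm: 575.0, delta_log_k: 0.45, template: rgb}
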