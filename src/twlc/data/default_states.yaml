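# Default structural and elastic characteristics of the four DNA forms used
# throughout the package.
#
# Columns:
#   Lp_nm             bending persistence length (energies in kBT)
#   Ltw_nm            twisting persistence length
#   contour_ratio     base-pair rise relative to B-DNA (rise_B = 0.33 nm)
#   helical_repeat_bp helical repeat, bp per turn (always positive)
#   handedness        +1 right-handed, -1 left-handed
#   mu_kBT            base-pairing free energy per bp relative to B-DNA
#   lambda            weight of the Fuller-writhe channel of the torque
#                     coupling in the transfer-matrix model, calibrated
#                     against the measured buckling boundary
states:
  - {state_id: B, Lp_nm: 50.0, Ltw_nm: 95.0, contour_ratio: 1.00, helical_repeat_bp: 10.4, handedness: 1,  mu_kBT: 0.0,  lambda: 4.3}
  - {state_id: L, Lp_nm: 7.0,  Ltw_nm: 15.0, contour_ratio: 1.35, helical_repeat_bp: 16.0, handedness: -1, mu_kBT: 5.0,  lambda: 4.3}
  - {state_id: P, Lp_nm: 15.0, Ltw_nm: 25.0, contour_ratio: 1.70, helical_repeat_bp: 3.0,  handedness: 1,  mu_kBT: 17.8, lambda: -0.5}
  - {state_id: S, Lp_nm: 15.0, Ltw_nm: 20.0, contour_ratio: 1.70, helical_repeat_bp: 35.0, handedness: 1,  mu_kBT: 5.1,  lambda: 4.3}
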