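# Species physiology table: monkey.
# Units: volumes L, flows L/h, pore radii nm, total_fcrn uM (referenced to total
# endosomal volume), j_iso L/h, aol_* cm (pore area-to-length density per pore class),
# body_weight kg, gfr L/h.
# Provenance: authored defaults representative of standard large-molecule PBPK
# physiology compilations (organ volumes/flows from common reference-body tables;
# two-pore constants from the classic two-pore literature: alpha_large 0.042,
# r_small 4.5 nm, r_large 25 nm, with leakier sinusoidal beds for liver/spleen;
# FcRn tissue shares and endothelial catabolism weights from literature-style
# distributions; the endosomal sub-space is an effective volume — 1.7% of
# tissue volume in human, 2.5% in monkey — absorbing endothelial uptake
# capacity so the pinocytosis rate constant can be held at its measured value).
# All values are editable; lung plasma_flow is derived at load time.
species: monkey
body_weight: 4.0
v_venous: 0.13
v_arterial: 0.065
gfr: 0.48
total_fcrn: 33.864
tissues:
  lung:
    total_volume: 0.057143
    v_vascular: 0.006286
    v_interstitial: 0.010857
    v_endosomal: 0.001429
    v_intracellular: 0.038571
    plasma_flow: 18.098196
    lymph_flow: 0.03619639
    fcrn_fraction: 0.06
    catabolism_weight: 0.05
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.003619639
    aol_small: 1257.2
    aol_large: 62.86
  adipose:
    total_volume: 0.742857
    v_vascular: 0.014857
    v_interstitial: 0.104
    v_endosomal: 0.018571
    v_intracellular: 0.605429
    plasma_flow: 1.65
    lymph_flow: 0.0033
    fcrn_fraction: 0.05
    catabolism_weight: 0.05
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.00033
    aol_small: 2971.4
    aol_large: 148.57
  bone:
    total_volume: 0.514286
    v_vascular: 0.015429
    v_interstitial: 0.051429
    v_endosomal: 0.012857
    v_intracellular: 0.434571
    plasma_flow: 0.99
    lymph_flow: 0.00198
    fcrn_fraction: 0.04
    catabolism_weight: 0.04
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.000198
    aol_small: 3085.8
    aol_large: 154.29
  brain:
    total_volume: 0.082857
    v_vascular: 0.002486
    v_interstitial: 0.014914
    v_endosomal: 0.002071
    v_intracellular: 0.063386
    plasma_flow: 1.98
    lymph_flow: 0.00396
    fcrn_fraction: 0.01
    catabolism_weight: 0.01
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.000396
    aol_small: 497.2
    aol_large: 24.86
  heart:
    total_volume: 0.018857
    v_vascular: 0.001886
    v_interstitial: 0.00264
    v_endosomal: 0.000471
    v_intracellular: 0.01386
    plasma_flow: 0.77
    lymph_flow: 0.00154
    fcrn_fraction: 0.02
    catabolism_weight: 0.02
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.000154
    aol_small: 377.2
    aol_large: 18.86
  kidney:
    total_volume: 0.017714
    v_vascular: 0.001771
    v_interstitial: 0.003543
    v_endosomal: 0.000443
    v_intracellular: 0.011957
    plasma_flow: 3.3
    lymph_flow: 0.0066
    fcrn_fraction: 0.06
    catabolism_weight: 0.08
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.00066
    aol_small: 354.2
    aol_large: 17.71
  muscle:
    total_volume: 1.657143
    v_vascular: 0.066286
    v_interstitial: 0.198857
    v_endosomal: 0.041429
    v_intracellular: 1.350571
    plasma_flow: 1.98
    lymph_flow: 0.00396
    fcrn_fraction: 0.22
    catabolism_weight: 0.23
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.000396
    aol_small: 13257.2
    aol_large: 662.86
  skin:
    total_volume: 0.188571
    v_vascular: 0.007543
    v_interstitial: 0.056571
    v_endosomal: 0.004714
    v_intracellular: 0.119743
    plasma_flow: 0.99
    lymph_flow: 0.00198
    fcrn_fraction: 0.16
    catabolism_weight: 0.21
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.000198
    aol_small: 1508.6
    aol_large: 75.43
  gut:
    total_volume: 0.094286
    v_vascular: 0.0066
    v_interstitial: 0.0264
    v_endosomal: 0.002357
    v_intracellular: 0.058929
    plasma_flow: 2.75
    lymph_flow: 0.0055
    fcrn_fraction: 0.12
    catabolism_weight: 0.14
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.00055
    aol_small: 1320.0
    aol_large: 66.0
  pancreas:
    total_volume: 0.008
    v_vascular: 0.00048
    v_interstitial: 0.00144
    v_endosomal: 0.0002
    v_intracellular: 0.00588
    plasma_flow: 0.385
    lymph_flow: 0.00077
    fcrn_fraction: 0.01
    catabolism_weight: 0.01
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 7.7e-05
    aol_small: 96.0
    aol_large: 4.8
  spleen:
    total_volume: 0.010857
    v_vascular: 0.002389
    v_interstitial: 0.002171
    v_endosomal: 0.000271
    v_intracellular: 0.006026
    plasma_flow: 0.495
    lymph_flow: 0.00099
    fcrn_fraction: 0.07
    catabolism_weight: 0.03
    alpha_large: 0.3
    alpha_small: 0.7
    r_small: 4.5
    r_large: 40.0
    j_iso: 9.9e-05
    aol_small: 477.8
    aol_large: 23.89
  liver:
    total_volume: 0.102857
    v_vascular: 0.011314
    v_interstitial: 0.020571
    v_endosomal: 0.002571
    v_intracellular: 0.068401
    plasma_flow: 2.64
    lymph_flow: 0.00528
    fcrn_fraction: 0.18
    catabolism_weight: 0.13
    alpha_large: 0.3
    alpha_small: 0.7
    r_small: 4.5
    r_large: 40.0
    j_iso: 0.000528
    aol_small: 2262.8
    aol_large: 113.14
  lymph_node:
    total_volume: 0.011429
    v_vascular: 0.000571
    v_interstitial: 0.005714
    v_endosomal: 0.000286
    v_intracellular: 0.004858
    plasma_flow: 0.132
    lymph_flow: 0.000264
    fcrn_fraction: 0.0
    catabolism_weight: 0.0
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 2.64e-05
    aol_small: 114.2
    aol_large: 5.71
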