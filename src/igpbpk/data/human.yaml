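# Species physiology table: human.
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
species: human
body_weight: 70.0
v_venous: 2.3
v_arterial: 1.1
gfr: 7.5
total_fcrn: 49.8
tissues:
  lung:
    total_volume: 1.0
    v_vascular: 0.11
    v_interstitial: 0.19
    v_endosomal: 0.017
    v_intracellular: 0.683
    plasma_flow: 164.529058
    lymph_flow: 0.32905812
    fcrn_fraction: 0.06
    catabolism_weight: 0.05
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.032905812
    aol_small: 22000.0
    aol_large: 1100.0
  adipose:
    total_volume: 13.0
    v_vascular: 0.26
    v_interstitial: 1.82
    v_endosomal: 0.221
    v_intracellular: 10.699
    plasma_flow: 15.0
    lymph_flow: 0.03
    fcrn_fraction: 0.05
    catabolism_weight: 0.05
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.003
    aol_small: 52000.0
    aol_large: 2600.0
  bone:
    total_volume: 9.0
    v_vascular: 0.27
    v_interstitial: 0.9
    v_endosomal: 0.153
    v_intracellular: 7.677
    plasma_flow: 9.0
    lymph_flow: 0.018
    fcrn_fraction: 0.04
    catabolism_weight: 0.04
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0018
    aol_small: 54000.0
    aol_large: 2700.0
  brain:
    total_volume: 1.45
    v_vascular: 0.0435
    v_interstitial: 0.261
    v_endosomal: 0.02465
    v_intracellular: 1.12085
    plasma_flow: 18.0
    lymph_flow: 0.036
    fcrn_fraction: 0.01
    catabolism_weight: 0.01
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0036
    aol_small: 8700.0
    aol_large: 435.0
  heart:
    total_volume: 0.33
    v_vascular: 0.033
    v_interstitial: 0.0462
    v_endosomal: 0.00561
    v_intracellular: 0.24519
    plasma_flow: 7.0
    lymph_flow: 0.014
    fcrn_fraction: 0.02
    catabolism_weight: 0.02
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0014
    aol_small: 6600.0
    aol_large: 330.0
  kidney:
    total_volume: 0.31
    v_vascular: 0.031
    v_interstitial: 0.062
    v_endosomal: 0.00527
    v_intracellular: 0.21173
    plasma_flow: 30.0
    lymph_flow: 0.06
    fcrn_fraction: 0.06
    catabolism_weight: 0.08
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.006
    aol_small: 6200.0
    aol_large: 310.0
  muscle:
    total_volume: 29.0
    v_vascular: 1.16
    v_interstitial: 3.48
    v_endosomal: 0.493
    v_intracellular: 23.867
    plasma_flow: 18.0
    lymph_flow: 0.036
    fcrn_fraction: 0.22
    catabolism_weight: 0.23
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0036
    aol_small: 232000.0
    aol_large: 11600.0
  skin:
    total_volume: 3.3
    v_vascular: 0.132
    v_interstitial: 0.99
    v_endosomal: 0.0561
    v_intracellular: 2.1219
    plasma_flow: 9.0
    lymph_flow: 0.018
    fcrn_fraction: 0.16
    catabolism_weight: 0.21
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0018
    aol_small: 26400.0
    aol_large: 1320.0
  gut:
    total_volume: 1.65
    v_vascular: 0.1155
    v_interstitial: 0.462
    v_endosomal: 0.02805
    v_intracellular: 1.04445
    plasma_flow: 25.0
    lymph_flow: 0.05
    fcrn_fraction: 0.12
    catabolism_weight: 0.14
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.005
    aol_small: 23100.0
    aol_large: 1155.0
  pancreas:
    total_volume: 0.14
    v_vascular: 0.0084
    v_interstitial: 0.0252
    v_endosomal: 0.00238
    v_intracellular: 0.10402
    plasma_flow: 3.5
    lymph_flow: 0.007
    fcrn_fraction: 0.01
    catabolism_weight: 0.01
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.0007
    aol_small: 1680.0
    aol_large: 84.0
  spleen:
    total_volume: 0.19
    v_vascular: 0.0418
    v_interstitial: 0.038
    v_endosomal: 0.00323
    v_intracellular: 0.10697
    plasma_flow: 4.5
    lymph_flow: 0.009
    fcrn_fraction: 0.07
    catabolism_weight: 0.03
    alpha_large: 0.3
    alpha_small: 0.7
    r_small: 4.5
    r_large: 40.0
    j_iso: 0.0009
    aol_small: 8360.0
    aol_large: 418.0
  liver:
    total_volume: 1.8
    v_vascular: 0.198
    v_interstitial: 0.36
    v_endosomal: 0.0306
    v_intracellular: 1.2114
    plasma_flow: 24.0
    lymph_flow: 0.048
    fcrn_fraction: 0.18
    catabolism_weight: 0.13
    alpha_large: 0.3
    alpha_small: 0.7
    r_small: 4.5
    r_large: 40.0
    j_iso: 0.0048
    aol_small: 39600.0
    aol_large: 1980.0
  lymph_node:
    total_volume: 0.2
    v_vascular: 0.01
    v_interstitial: 0.1
    v_endosomal: 0.0034
    v_intracellular: 0.0866
    plasma_flow: 1.2
    lymph_flow: 0.0024
    fcrn_fraction: 0.0
    catabolism_weight: 0.0
    alpha_large: 0.042
    alpha_small: 0.958
    r_small: 4.5
    r_large: 25.0
    j_iso: 0.00024
    aol_small: 2000.0
    aol_large: 100.0
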