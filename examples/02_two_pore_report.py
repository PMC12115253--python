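"""Two-pore transport diagnostics: how protein size gates tissue access.

Prints the per-tissue reflection coefficients, permeability-surface-area
products and Peclet numbers for a full-size IgG (150 kDa) and a small
bispecific T-cell engager (55 kDa).
"""

from igpbpk import load_physiology, stokes_radius
from igpbpk.twopore import pore_report

phys = load_physiology("human")
for mw in (150_000.0, 55_000.0):
    print(f"\n=== MW {mw:,.0f} g/mol, Stokes radius "
          f"{stokes_radius(mw):.2f} nm ===")
    df = pore_report(phys, mw)
    print(df.loc[:, ["tissue", "sigma_small", "sigma_large",
                     "ps_large_L_per_h", "peclet_large"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# A 150 kDa IgG (a_e ~ 4.8 nm) is fully excluded from the 4.5 nm small pores
# (sigma_small = 1) and crosses mainly by large-pore convection; the 55 kDa
# format also passes the small pores, so its interstitial access is wider.
# Liver and spleen, modelled with leaky sinusoidal large pores, show the
# lowest reflection.
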