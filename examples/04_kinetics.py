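"""Fit apparent Michaelis-Menten parameters from initial-rate data.

Simulates rate measurements for a slow parent enzyme and a fast evolved
variant on the default 8-point substrate design, fits both curves, and
reports catalytic efficiencies and the fold-improvement in turnover.
"""

from mlde.kinetics import fit_mm, relative_kcat, slope_to_rate
from mlde.synthetic import simulate_mm_dataset

ENZYME_UM = 1.0

parent_data = simulate_mm_dataset(kcat=0.49, km=11.9, enzyme_conc=ENZYME_UM,
                                  noise_cv=0.03, seed=31)
evolved_data = simulate_mm_dataset(kcat=31.5, km=143.5, enzyme_conc=ENZYME_UM,
                                   noise_cv=0.03, seed=32)

parent = fit_mm(parent_data, enzyme_conc=ENZYME_UM)
evolved = fit_mm(evolved_data, enzyme_conc=ENZYME_UM)

for label, fit in (("parent", parent), ("evolved", evolved)):
    print(f"{label}: kcat_app = {fit.kcat_app:.2f} +/- {fit.kcat_se:.2f} 1/min, "
          f"KM_app = {fit.km_app:.1f} +/- {fit.km_se:.1f} uM, "
          f"kcat/KM = {fit.efficiency:.1f} 1/min/mM"
          f"{'' if fit.saturated else '  [saturation not reached]'}")

rel = relative_kcat(evolved, parent)
print(f"turnover improvement: {rel.fold:.1f}-fold (reported as {rel.rounded}x)")
print(f"for context, a UV-assay slope of 0.0622 dA/min in a 1-cm path at this")
print(f"enzyme loading is a turnover of {slope_to_rate(0.0622, 6220.0, 1.0, ENZYME_UM):.1f} 1/min")
print("apparent parameters: measured under the coupled cofactor-recycling")
print("assay, not true single-substrate conditions.")
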