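"""Total HetCA on a simulated 12-fraction study.

Simulates ten standard compounds (five radical scavengers, five inactive)
combined into twelve fractions, correlates the bucketed spectra with the
% DPPH inhibition of each fraction, and reports the most activity-correlated
resonances.  High-r, positive-covariance buckets are the "deep red" peaks a
pseudospectrum would show — candidate resonances of the bioactive
constituents.
"""

import numpy as np

import hetcakit as hk

design = hk.preset("artfrct", seed=0, noise=False, jitter=False)
spectra, activity, truth = hk.simulate(design)
print(f"{len(spectra)} fractions, inhibition "
      f"{activity.mean_inhibition.min():.1f}-{activity.mean_inhibition.max():.1f} %")

buckets = hk.bucket(hk.apply_exclusions(spectra), width=0.01)
ps = hk.hetca(buckets, activity)

# deep-red variables: high correlation, ranked by covariance (peak height)
red = np.flatnonzero((ps.correlation >= 0.9) & (ps.covariance > 0))
top = red[np.argsort(ps.covariance[red])[::-1][:5]]
print("\ntallest deep-red resonances (ppm, r, covariance):")
for j in top:
    print(f"  {ps.ppm_centers[j]:6.3f} ppm   r={ps.correlation[j]:+.3f}   "
          f"c={ps.covariance[j]:+.1f}")

actives = [c.name for c in design.compounds if truth.active_labels[c.name]]
peaks = {c.name: [p for p, _, _ in c.peaks] for c in design.compounds}
print(f"\ntrue actives {actives} have peaks at:")
for name in actives:
    print(f"  {name}: {[round(p, 3) for p in peaks[name]]}")
print("\nthe top-correlated ppm values coincide with active-compound peaks;")
print("r near +1 with positive covariance marks resonances that rise and")
print("fall with the bioassay response across the fraction series.")

hk.render_pseudospectrum(ps, hk.PlotSpec(title="total HetCA, 12 fractions"),
                         "pseudospectrum_artfrct.png")
print("\nwrote pseudospectrum_artfrct.png")
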