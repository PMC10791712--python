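"""Regulatory assessment, trophic state index, and PCA diagnostics.

Compliance scores the fraction of samples meeting the bathing-water maxima
(0.51+ after rounding = compliance); ecological status averages 1/2/3
class points per observation.  The trophic state index combines the TP and
TN components; the PCA block reports factorability diagnostics (KMO,
Bartlett) and the Kaiser-retained components.
"""

import emwater as ew

ds, _ = ew.exclude_constant_parameters(ew.generate(ew.default_config(), 1))

assessment = ew.assessment_table(ds)
print("regulatory assessment (scores rounded to 2 decimals):")
print(assessment.round(2).to_string())

tsi = ew.tsi_by_period(ds)
print("\ntrophic state by period (higher = more eutrophic):")
print(tsi.round(2).to_string())
change = ew.percent_change(tsi.loc["before", "tsi"], tsi.loc["after", "tsi"])
print(f"combined TSI change after treatment: {change:+.2f}%")

res = ew.pca(ds)
print(f"\nPCA: n={res.n_observations}, KMO={res.kmo:.3f}, "
      f"Bartlett chi2={res.bartlett_chi2:.1f} (df={res.bartlett_df}, "
      f"p={res.bartlett_p:.2g})")
print(f"retained components (eigenvalue > 1): {res.n_retained}")
for i, (ev, pct) in enumerate(
    zip(res.eigenvalues[: res.n_retained],
        res.explained_pct[: res.n_retained]), 1
):
    print(f"  PC{i}: eigenvalue {ev:.2f}, {pct:.1f}% of variance")

corr = ew.spearman_matrix(ds)
print("\nstrong significant Spearman pairs (|rho| >= 0.70):")
for a, b, r in corr.strong_pairs():
    print(f"  {a} / {b}: {r:+.2f}")
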