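"""Histone-PTM isoform quantification with isobaric deconvolution.

Starts from a synthetic chromatogram-area table of the kind a targeted-MS
tool exports.  Coeluting isobaric isoforms share one MS1 area; their
split is recovered from three modification-unique MS2 fragment integrals,
then every isoform is expressed as a percentage of its peptide.
"""

from nchipkit import isoform_percentages, resolve_isobaric, simulate_peptide_table

table, truth = simulate_peptide_table(
    n_peptides=6, isobaric_pairs=2, seed=4, noise_cv=0.05
)
resolved = resolve_isobaric(table)
pct = isoform_percentages(resolved)

merged = pct.merge(truth, on=["peptide", "modification"])
print(merged[["peptide", "modification", "percentage", "true_percentage"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
err = (merged["percentage"] - merged["true_percentage"]).abs().max()
print(f"max |recovered - planted| = {err:.2f} percentage points at 5% "
      "fragment noise")
# percentages within each peptide sum to 100; isobaric pairs are split in
# proportion to their mean fragment integrals, conserving the shared area
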