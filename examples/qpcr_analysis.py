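"""ChIP-qPCR percent input and 2^-ddCt relative expression.

Percent input adjusts the input Ct for the reserved chromatin fraction
and reports 100 * 2^(Ct'_input - Ct_IP).  Relative expression normalizes
to a reference gene, calibrates to a control condition, and reports the
error-bar range 2^(-ddCt +/- SEM).
"""

import pandas as pd

from nchipkit import ddct_expression, percent_input

chip = pd.DataFrame(
    [
        ("CCL5_TSS", "control", 1, "IP", 24.1), ("CCL5_TSS", "control", 1, "input", 21.7),
        ("CCL5_TSS", "control", 2, "IP", 24.4), ("CCL5_TSS", "control", 2, "input", 21.9),
        ("CCL5_TSS", "knockdown", 1, "IP", 22.8), ("CCL5_TSS", "knockdown", 1, "input", 21.8),
        ("CCL5_TSS", "knockdown", 2, "IP", 23.0), ("CCL5_TSS", "knockdown", 2, "input", 21.6),
    ],
    columns=["target", "condition", "replicate", "role", "ct"],
)
print(percent_input(chip, input_fraction=0.1).to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))
# higher percent input after knockdown = more chromatin recovered, i.e.
# increased acetylation at this locus

expr = pd.DataFrame(
    [(g, c, r, "cDNA", ct + (0.2 * (r - 2) if g == "FST" else 0.0))
     for g, c, ct in [("FST", "control", 26.0), ("FST", "knockdown", 24.4),
                      ("HPRT1", "control", 20.0), ("HPRT1", "knockdown", 20.1)]
     for r in (1, 2, 3)],
    columns=["target", "condition", "replicate", "role", "ct"],
)
print(ddct_expression(expr, "HPRT1", "control").to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))
# fold_change > 1 means upregulation relative to the control condition;
# the range columns are the asymmetric SEM error bars
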