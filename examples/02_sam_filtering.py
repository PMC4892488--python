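"""SAM-style differential pre-filtering.

The moderated statistic d = (mean_test - mean_ref) / (s + s0) is compared,
rank by rank, with its permutation expectation; genes deviating by more
than delta are selected.  On the synthetic scenario the 50 genes planted
with a 3-SD shift should dominate any tight selection.
"""

import pandas as pd

from coexdiff import default_paper_like_scenario, sam_select, simulate_two_condition

cfg = default_paper_like_scenario(seed=1)
expr_ref, expr_test, groups, truth = simulate_two_condition(cfg)
expr = pd.concat([expr_ref, expr_test], axis=1)

for delta in (0.5, 2.0, 8.0):
    res = sam_select(expr, groups, delta=delta, n_perm=50, seed=1)
    sel = set(res.selected_genes)
    true_de = set(truth.de_flag.index[truth.de_flag])
    precision = len(sel & true_de) / len(sel) if sel else float("nan")
    print(f"delta={delta:4.1f}: {len(sel):4d} genes selected "
          f"(s0={res.s0:.3f}), precision vs planted shifts {precision:.2f}")

# Larger delta tightens the band around the permutation expectation: fewer
# selections, higher precision.  The monotone nesting of selections in
# delta is a structural property of the banding rule.
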