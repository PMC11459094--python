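"""Compare SAW and VIKOR rankings on the bundled drug panel.

SAW normalizes each criterion, multiplies by the weights and sums (higher
total = better); VIKOR blends distance-to-ideal aggregates.  The two
methods agree on the extremes but can reorder the mid-field.
"""

import pandas as pd

from toporank import prioritize
from toporank.datasets import ev_ranking_correlations, load_lung_drug_indices

matrix = load_lung_drug_indices()
r = ev_ranking_correlations()

vikor_res = prioritize(matrix, r, method="vikor")
saw_res = prioritize(matrix, r, method="saw")

comparison = pd.DataFrame(
    {
        "vikor_Q": vikor_res.q.round(4),
        "vikor_rank": vikor_res.rank_q,
        "saw_total": saw_res.totals.round(4),
        "saw_rank": saw_res.ranks,
    }
).sort_values("vikor_rank")
print(comparison.to_string())

agree = (comparison["vikor_rank"] == comparison["saw_rank"]).sum()
print(f"\nranks agree for {agree} of {len(comparison)} drugs")

# VIKOR rewards balanced closeness to the ideal (small worst-case regret R);
# SAW is a pure weighted sum, so a drug strong on heavy criteria can rank
# higher under SAW even with one very poor criterion.
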