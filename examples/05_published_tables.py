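"""Worked example: the reporting utilities on the published summaries.

The reference grids bundled with the package (a four-cancer TCGA
comparison's c-index table and its twelve MERGE model compositions) feed
the same aggregation code the benchmark uses, reproducing the published
margins and source shares.
"""

from omicox import aggregate_averages, source_distribution
from omicox.tables import ALGORITHMS, COHORTS, MERGE_COMPOSITIONS, cindex_frame

grid = cindex_frame()
print("per-cohort Average rows (recomputed from the per-cell values):")
for cohort in COHORTS:
    print(f"  {cohort:5s}", aggregate_averages(grid.loc[cohort]).to_dict())

print("\nper-cohort mean c-index excluding MUT (0-1 scale):")
for cohort in ("BRCA", "LUAD", "OV", "GBM"):
    cells = grid.loc[cohort].drop(columns="MUT")
    print(f"  {cohort:5s} {cells.mean().mean() / 100:.2f}")

shares = source_distribution(MERGE_COMPOSITIONS.values())
print("\npooled MERGE source shares (%):")
print(shares.to_string())
# The pooled shares (EXPR 54, MIRNA 6, CNA 27, MUT 14) quantify how often
# each data source is chosen when models may draw on all four at once.
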