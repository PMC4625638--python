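"""Source-specific feature filters.

EXPR/MIRNA pass a correlation filter (keep a feature only if it has some
partner with |Spearman rho| above threshold) followed by a quantization
filter that removes near-invariant features.  CNA features are ranked by
the log-rank p-value of a univariate Cox median split and the top fraction
kept.  MUT genes are ranked by mutation frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix, SurvivalData, ValidationError
from .survival import FitError, fit_cox, logrank_median_split, prognostic_index


@dataclass
class FilterConfig:
    rho_threshold: float = 0.6
    n_bins: int = 5
    min_occupied_bins: int = 3  # "more than two" occupied segments
    cna_top_fraction: float = 0.10
    mut_top_fraction: float = 0.10  # dataset-specific in the source study

    def __post_init__(self) -> None:
        for frac in (self.cna_top_fraction, self.mut_top_fraction):
            if not 0 < frac <= 1:
                raise ValidationError("top fractions must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if not 1 <= self.min_occupied_bins <= self.n_bins:
            raise ValidationError("min_occupied_bins must lie in [1, n_bins]")


def _keep_count(fraction: float, total: int) -> int:
    # ceiling so a positive fraction never keeps zero features
    return min(total, math.ceil(fraction * total))


def correlation_filter(matrix: OmicsMatrix, rho_threshold: float = 0.6) -> list:
    """Keep features having |Spearman rho| > threshold with any other feature."""
    if matrix.source == "MUT":
        raise ValidationError("correlation filter applies to continuous sources")
    values = matrix.values
    p = values.shape[0]
    if p < 2:
        raise ValidationError("correlation filter needs at least 2 features")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 0.0)
    rho = np.nan_to_num(rho, nan=0.0)  # constant features correlate with nothing
    keep = np.abs(rho).max(axis=1) > rho_threshold
    return [fid for fid, k in zip(matrix.feature_ids, keep) if k]


def quantization_filter(
    matrix: OmicsMatrix, n_bins: int = 5, min_occupied_bins: int = 3
) -> list:
    """Keep features whose values occupy >= min_occupied_bins of n_bins
    equal-width bins over the feature's own observed range.  Constant
    features (zero range) occupy a single bin and are dropped."""
    kept = []
    for fid, row in zip(matrix.feature_ids, matrix.values):
        lo, hi = row.min(), row.max()
        if hi <= lo:
            continue
        counts, _ = np.histogram(row, bins=n_bins, range=(lo, hi))
        if int((counts > 0).sum()) >= min_occupied_bins:
            kept.append(fid)
    return kept


def cna_survival_filter(
    matrix: OmicsMatrix,
    survival: SurvivalData,
    top_fraction: float = 0.10,
    return_stats: bool = False,
):
    """Rank CNA features by univariate log-rank p (median split of the
    prognostic index) and keep the top fraction.

    Non-converging fits are ranked last.  Ties in p-value break by feature
    id so the kept set is deterministic.
    """
    records = []
    X = matrix.df.T  # patients x features
    for fid in matrix.feature_ids:
        try:
            fit = fit_cox(X[[fid]], survival)
            if not fit.converged:
                raise FitError("did not converge")
            pi = prognostic_index(fit, X[[fid]])
            _, p, _ = logrank_median_split(pi.to_numpy(), survival)
        except FitError:
            p = np.inf
        records.append((p, fid))
    stats_df = pd.DataFrame(records, columns=["logrank_p", "feature_id"])
    stats_df = stats_df.sort_values(["logrank_p", "feature_id"], kind="stable")
    n_keep = _keep_count(top_fraction, len(records))
    kept = stats_df["feature_id"].head(n_keep).tolist()
    if return_stats:
        return kept, stats_df.set_index("feature_id")
    return kept


def mutation_frequency_filter(matrix: OmicsMatrix, top_fraction: float) -> list:
    """Keep the most frequently mutated genes (ties break by feature id)."""
    if matrix.source != "MUT":
        raise ValidationError("mutation filter applies to MUT matrices")
    counts = matrix.values.sum(axis=1)
    if counts.sum() == 0:
        warnings.warn("all-zero mutation matrix; nothing to keep", stacklevel=2)
        return []
    order = sorted(zip(matrix.feature_ids, counts), key=lambda t: (-t[1], t[0]))
    n_keep = _keep_count(top_fraction, len(order))
    return [fid for fid, _ in order[:n_keep]]


def filter_source(
    matrix: OmicsMatrix, survival: SurvivalData, config: FilterConfig
) -> OmicsMatrix:
    """Apply the source-appropriate filter pipeline and subset the matrix."""
    if matrix.source in ("EXPR", "MIRNA"):
        kept = correlation_filter(matrix, config.rho_threshold)
        sub = matrix.subset_features(kept) if kept else matrix.subset_features([])
        if kept:
            kept = quantization_filter(sub, config.n_bins, config.min_occupied_bins)
    elif matrix.source == "CNA":
        kept = cna_survival_filter(matrix, survival, config.cna_top_fraction)
    else:
        kept = mutation_frequency_filter(matrix, config.mut_top_fraction)
    return matrix.subset_features(kept)
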