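"""Orchestration of the full comparison and its reporting utilities.

The grid crosses data types (EXPR, MIRNA, CNA, MUT, MERGE) with the three
selectors (CPSO, NFS, LASSO).  Evaluation follows the shared protocol:
CPSO and NFS models trained on continuous data are scored on a held-out
blind-test third of the patients; LASSO models, and every model trained
on sparse binary mutation data, are scored by resubstitution.  One
event-stratified train/test split per cohort (derived from the master
seed) is shared across all cells so that agreement comparisons are made
on identical patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cpso import CPSOConfig, run_cpso
from .io import SurvivalData
from .lasso import LassoConfig, NoModelError, run_lasso
from .metabase import build_metabase
from .nfs import NFSConfig, run_nfs
from .survival import (
    EvalResult,
    FitError,
    SurvivalModel,
    cohen_kappa,
    evaluate_model,
    stratified_split,
)
from .synthetic import (
    MODERATE_EFFECTS,
    SyntheticConfig,
    apply_censoring,
    calibrate_censoring,
    generate_cohort,
)

DATA_TYPES = ("EXPR", "MIRNA", "CNA", "MUT", "MERGE")
ALGORITHMS = ("CPSO", "NFS", "LASSO")


@dataclass
class BenchmarkCell:
    data_type: str
    algorithm: str
    model: SurvivalModel | None
    eval: EvalResult | None
    mode: str
    error: str | None = None


@dataclass
class BenchmarkResult:
    cells: dict = field(default_factory=dict)  # (data_type, algorithm) -> cell
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)

    def cindex_frame(self, scale: int = 100) -> pd.DataFrame:
        """Data-type x algorithm grid of c-index on the 0-100 scale."""
        frame = pd.DataFrame(
            index=list(DATA_TYPES), columns=list(ALGORITHMS), dtype=float
        )
        for (dt, alg), cell in self.cells.items():
            if cell.eval is not None:
                frame.loc[dt, alg] = cell.eval.c_index * scale
        return frame


def evaluation_mode(data_type: str, algorithm: str) -> str:
    if algorithm == "LASSO" or data_type == "MUT":
        return "resubstitution"
    return "blind_test"


def _matrix_for(data_type, matrices, metabase):
    return metabase if data_type == "MERGE" else matrices[data_type]


def run_cell(
    data_type: str,
    algorithm: str,
    matrices: dict,
    metabase,
    survival: SurvivalData,
    network,
    targets,
    train_ids,
    test_ids,
    configs: dict,
) -> BenchmarkCell:
    mode = evaluation_mode(data_type, algorithm)
    matrix = _matrix_for(data_type, matrices, metabase)
    if mode == "blind_test":
        train_m = matrix.subset_patients(train_ids)
        train_s = survival.subset(train_ids)
        eval_m, eval_s = matrix.subset_patients(test_ids), survival.subset(test_ids)
    else:
        train_m, train_s = matrix, survival
        eval_m, eval_s = matrix, survival
    try:
        if algorithm == "CPSO":
            model = run_cpso(train_m, train_s, configs["CPSO"])
        elif algorithm == "NFS":
            use_targets = targets if data_type in ("MIRNA", "MERGE") else None
            model = run_nfs(train_m, train_s, network, configs["NFS"], targets=use_targets)
        else:
            model = run_lasso(train_m, train_s, configs["LASSO"])
        result = evaluate_model(model.fit, eval_m.df.T, eval_s, mode)
        return BenchmarkCell(data_type, algorithm, model, result, mode)
    except (NoModelError, FitError, ValueError) as exc:
        return BenchmarkCell(data_type, algorithm, None, None, mode, error=str(exc))


def run_benchmark(
    matrices: dict,
    survival: SurvivalData,
    network,
    targets,
    configs: dict | None = None,
    data_types=DATA_TYPES,
    algorithms=ALGORITHMS,
    seed: int = 0,
) -> BenchmarkResult:
    """Populate the (data type x algorithm) grid on one aligned cohort.

    ``matrices`` must already be filtered and aligned; the MERGE metabase
    is built here.  Cell-level failures are recorded, never raised.
    """
    configs = dict(configs or {})
    configs.setdefault("CPSO", CPSOConfig(seed=seed))
    configs.setdefault("NFS", NFSConfig(seed=seed))
    configs.setdefault("LASSO", LassoConfig(seed=seed))
    metabase = build_metabase(matrices) if "MERGE" in data_types else None
    train_ids, test_ids = stratified_split(survival, seed=seed)
    result = BenchmarkResult(train_ids=train_ids, test_ids=test_ids)
    for dt in data_types:
        for alg in algorithms:
            result.cells[(dt, alg)] = run_cell(
                dt, alg, matrices, metabase, survival, network, targets,
                train_ids, test_ids, configs,
            )
    return result


# ---------------------------------------------------------------------------
# reporting


def round_half_up(x) -> int:
    return int(np.floor(np.asarray(x, dtype=float) + 0.5))


def aggregate_averages(grid: pd.DataFrame, axis: int = 0) -> pd.Series:
    """Margin means of a c-index grid (0-100 scale), half-up rounded.

    Cells without models (NaN) are excluded from their margin; an all-NaN
    margin raises.
    """
    means = grid.mean(axis=axis, skipna=True)
    if means.isna().any():
        raise ValueError("a margin contains no models")
    return means.map(round_half_up)


def source_distribution(compositions) -> pd.DataFrame:
    """Counts and integer-rounded percentages per source.

    ``compositions`` is an iterable of per-model source->count mappings
    (or SurvivalModel instances, whose tagged sources are counted).
    """
    sources = ("EXPR", "MIRNA", "CNA", "MUT")
    totals = dict.fromkeys(sources, 0)
    for comp in compositions:
        if isinstance(comp, SurvivalModel):
            comp = pd.Series(comp.sources).value_counts().to_dict()
        for src in comp:
            if src not in totals:
                raise ValueError(f"untagged source {src!r}")
            totals[src] += comp[src]
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no features in any model")
    rows = {
        src: {"count": totals[src], "percent": round_half_up(100 * totals[src] / grand)}
        for src in sources
    }
    out = pd.DataFrame(rows).T
    out.attrs["total_features"] = grand
    return out


def kappa_matrix(result_or_cells) -> pd.DataFrame:
    """Cohen's kappa of median-split risk groups across all model pairs.

    For each pair of populated cells the prognostic indices are restricted
    to the patients common to both evaluations, each index is
    dichotomized at its own median over those patients, and kappa is
    computed.  Cells without models are omitted.
    """
    if isinstance(result_or_cells, BenchmarkResult):
        cells = result_or_cells.cells
    else:
        cells = result_or_cells
    populated = {
        key: cell for key, cell in cells.items() if cell.eval is not None
    }
    labels = [f"{dt}/{alg}" for dt, alg in populated]
    keys = list(populated)
    n = len(keys)
    out = pd.DataFrame(np.full((n, n), np.nan), index=labels, columns=labels)
    for i in range(n):
        for j in range(i, n):
            pi_a = populated[keys[i]].eval.prognostic_index
            pi_b = populated[keys[j]].eval.prognostic_index
            common = pi_a.index.intersection(pi_b.index)
            if len(common) < 2:
                continue
            a = (pi_a[common] > pi_a[common].median()).astype(int)
            b = (pi_b[common] > pi_b[common].median()).astype(int)
            k = cohen_kappa(a.to_numpy(), b.to_numpy())
            out.iloc[i, j] = out.iloc[j, i] = k
    return out


def cross_data_type_mean_kappa(kmat: pd.DataFrame) -> float:
    """Mean kappa over pairs whose data types differ."""
    values = []
    for i, a in enumerate(kmat.index):
        for j in range(i + 1, len(kmat.columns)):
            b = kmat.columns[j]
            if a.split("/")[0] != b.split("/")[0]:
                v = kmat.iloc[i, j]
                if np.isfinite(v):
                    values.append(v)
    if not values:
        raise ValueError("no cross-data-type pairs")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# simulation experiments


def _select(algorithm, matrix, survival, network, targets, configs):
    if algorithm == "CPSO":
        return run_cpso(matrix, survival, configs["CPSO"])
    if algorithm == "NFS":
        return run_nfs(matrix, survival, network, configs["NFS"], targets=targets)
    return run_lasso(matrix, survival, configs["LASSO"])


def recovery_experiment(
    n_seeds: int = 20,
    algorithm: str = "CPSO",
    data_type: str = "EXPR",
    gen_config: SyntheticConfig | None = None,
    configs: dict | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Planted-signal recovery under the blind-test protocol.

    For each seed a fresh cohort is generated, the selector is trained on
    the two-thirds training split of one data source, and the model is
    scored on the blind-test third.  Returns per-seed blind-test c-index
    and the number of planted features recovered.
    """
    rows = []
    for s in range(n_seeds):
        seed = (base_seed + s) % 2**31
        cfg = gen_config or SyntheticConfig(n_patients=300, censoring_target=0.3)
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed})
        cohort = generate_cohort(cfg)
        matrix = cohort.matrices[data_type]
        sel_configs = dict(configs or {})
        sel_configs.setdefault("CPSO", CPSOConfig(k=3, iterations=40, runs=2, swarm_size=15, bootstrap_B=5, seed=seed))
        sel_configs.setdefault("NFS", NFSConfig(seed=seed))
        sel_configs.setdefault("LASSO", LassoConfig(target_size=5, n_folds=5, seed=seed))
        train_ids, test_ids = stratified_split(cohort.survival, seed=seed)
        train_m = matrix.subset_patients(train_ids)
        train_s = cohort.survival.subset(train_ids)
        targets = cohort.target_map if data_type == "MIRNA" else None
        model = _select(algorithm, train_m, train_s, cohort.network, targets, sel_configs)
        result = evaluate_model(
            model.fit, matrix.subset_patients(test_ids).df.T,
            cohort.survival.subset(test_ids), "blind_test",
        )
        planted = set(cohort.truth.planted.get(data_type, []))
        rows.append({
            "seed": seed,
            "c_index": result.c_index,
            "n_planted_recovered": len(planted & set(model.feature_ids)),
            "model_size": model.size,
        })
    return pd.DataFrame(rows)


def censoring_agreement_experiment(
    censoring_levels=(0.0, 0.8),
    n_seeds: int = 20,
    data_types=("EXPR", "MIRNA", "CNA"),
    gen_config: SyntheticConfig | None = None,
    lasso_config: LassoConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Cross-data-type agreement as a function of the censoring rate.

    Per seed, one uncensored cohort is generated; each censoring level is
    then applied to the *same* event times, so cohorts are matched except
    for censoring.  A penalized Cox model is selected per data type and
    the mean Cohen's kappa over cross-data-type pairs of median-split
    risk groups is recorded.  Returns one row per (seed, level).
    """
    rows = []
    for s in range(n_seeds):
        seed = (base_seed + s) % 2**31
        cfg = gen_config or SyntheticConfig(
            n_patients=250, effect_sizes={k: tuple(v) for k, v in MODERATE_EFFECTS.items()}
        )
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed, "censoring_target": 0.0})
        cohort = generate_cohort(cfg)
        event_times = cohort.survival.time
        cens_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
        for level in censoring_levels:
            rate = calibrate_censoring(event_times, level)
            survival, achieved = apply_censoring(
                cohort.survival.patient_ids, event_times, rate, cens_rng
            )
            kappas = []
            pis = {}
            for dt in data_types:
                cfg_l = lasso_config or LassoConfig(target_size=5, n_folds=5)
                cfg_l = LassoConfig(**{**cfg_l.__dict__, "seed": seed})
                try:
                    model = run_lasso(cohort.matrices[dt], survival, cfg_l)
                except (NoModelError, FitError):
                    continue
                pis[dt] = pd.Series(
                    cohort.matrices[dt].df.T[model.feature_ids].to_numpy() @ model.beta,
                    index=cohort.matrices[dt].patient_ids,
                )
            names = list(pis)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a = (pis[names[i]] > pis[names[i]].median()).astype(int)
                    b = (pis[names[j]] > pis[names[j]].median()).astype(int)
                    k = cohen_kappa(a.to_numpy(), b.to_numpy())
                    if np.isfinite(k):
                        kappas.append(k)
            rows.append({
                "seed": seed,
                "censoring_target": level,
                "achieved_censoring": achieved,
                "mean_cross_kappa": float(np.mean(kappas)) if kappas else np.nan,
                "n_pairs": len(kappas),
            })
    return pd.DataFrame(rows)


def sign_test_decrease(low: np.ndarray, high: np.ndarray) -> float:
    """One-sided sign-test p that the paired values decrease (low > high)."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    diff = low - high
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    wins = int((diff > 0).sum())
    return float(stats.binomtest(wins, diff.size, 0.5, alternative="greater").pvalue)
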