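"""Synthetic multi-omic survival cohorts with planted prognostic structure.

The generator emulates a TCGA-style cohort in which the same patients are
profiled on four platforms — mRNA expression (EXPR), miRNA expression
(MIRNA), segmented copy number (CNA), and binary somatic mutation calls
(MUT) — together with a clinical survival table, a gene interaction
network, and a miRNA->target map.

A small set of *planted* features per source carries the prognostic
signal.  Planted features load on a shared per-patient latent risk factor,
mimicking the fact that in real tumours copy-number, expression and miRNA
readouts partially reflect the same underlying biology; the hazard is
proportional to ``exp(eta)`` where ``eta`` is the linear predictor over
all planted features.  Event times are Weibull (shape 1 = exponential by
default); censoring times are exponential with the rate calibrated by
bisection against the realized event-time sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    InteractionNetwork,
    MirnaTargetMap,
    OmicsMatrix,
    SurvivalData,
    ValidationError,
    ensure_dir,
    write_clinical,
    write_edge_list,
    write_matrix,
    write_target_map,
)

import pandas as pd

DEFAULT_FEATURES = {"EXPR": 60, "MIRNA": 30, "CNA": 40, "MUT": 30}
DEFAULT_PLANTED = {"EXPR": 3, "MIRNA": 2, "CNA": 2, "MUT": 2}
DEFAULT_EFFECTS = {
    "EXPR": (1.2, 1.0, 0.8),
    "MIRNA": (0.8, 0.7),
    "CNA": (0.8, 0.6),
    "MUT": (0.7, 0.6),
}

# log-hazard effects giving an oracle c-index around 0.7, the range observed
# for real tumour cohorts; used by experiments that need realistic (not
# saturated) model identification
MODERATE_EFFECTS = {
    "EXPR": (0.6, 0.5, 0.4),
    "MIRNA": (0.4, 0.35),
    "CNA": (0.4, 0.3),
    "MUT": (0.35, 0.3),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one generated cohort.

    ``effect_sizes`` are per-planted-feature Cox log-hazard coefficients;
    ``latent_loading`` controls how strongly planted continuous features
    correlate across sources through the shared latent risk factor.
    """

    n_patients: int = 200
    n_features_per_source: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    n_planted: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    effect_sizes: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_EFFECTS.items()})
    censoring_target: float = 0.3
    baseline_scale: float = 365.0  # days
    weibull_shape: float = 1.0
    mutation_frequency_range: tuple = (0.02, 0.3)
    network_degree_param: float = 2.0
    latent_loading: float = 0.7
    hub_degree: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not 0 <= self.censoring_target < 1:
            raise ValidationError("censoring_target must lie in [0, 1)")
        lo, hi = self.mutation_frequency_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("mutation frequencies must lie in (0, 1)")
        if self.baseline_scale <= 0 or self.weibull_shape <= 0:
            raise ValidationError("scale and shape must be positive")
        if self.network_degree_param <= 0:
            raise ValidationError("network_degree_param must be positive")
        for src, p in self.n_features_per_source.items():
            if p <= 0:
                raise ValidationError(f"{src}: feature count must be positive")
            k = self.n_planted.get(src, 0)
            if k < 0 or k > p:
                raise ValidationError(f"{src}: n_planted must lie in [0, {p}]")

    def coefficients(self, source: str) -> np.ndarray:
        """Planted coefficients for one source, broadcast if scalar."""
        k = self.n_planted.get(source, 0)
        eff = self.effect_sizes.get(source, ())
        if np.isscalar(eff):
            return np.full(k, float(eff))
        eff = np.asarray(eff, dtype=float)
        if eff.size < k:
            raise ValidationError(f"{source}: need {k} effect sizes, got {eff.size}")
        return eff[:k]


@dataclass
class TruthRecord:
    planted: dict  # source -> list of feature ids
    coefficients: dict  # source -> array of log-hazard coefficients
    achieved_censoring: float
    seed: int


@dataclass
class Cohort:
    survival: SurvivalData
    matrices: dict  # source -> OmicsMatrix
    network: InteractionNetwork
    target_map: MirnaTargetMap
    truth: TruthRecord


def calibrate_censoring(event_times, target: float):
    """Exponential censoring rate giving the requested censoring fraction.

    With censoring time ``C ~ Exp(rate)`` independent of the event time, a
    patient with event time ``t`` is censored with probability
    ``1 - exp(-rate * t)``; the expected censoring fraction over the sample
    is monotone in the rate, so bisection solves for it.  ``target = 0``
    returns rate 0, meaning no censoring (censoring time = +infinity).
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0 or event_times.min() <= 0:
        raise ValidationError("event times must be positive")
    if not 0 <= target < 1:
        raise ValidationError("censoring target must lie in [0, 1)")
    if target == 0:
        return 0.0

    def frac(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * event_times)))

    lo, hi = 0.0, 1.0 / event_times.mean()
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12 / event_times.mean():
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _feature_ids(source: str, p: int) -> list:
    prefix = {"EXPR": "G", "MIRNA": "MIR", "CNA": "CNR", "MUT": "G"}[source]
    return [f"{prefix}{i:04d}" for i in range(p)]


def _continuous_matrix(rng, p, n, planted_idx, loading, u, block=None, modules=False):
    x = rng.standard_normal((p, n))
    if block:
        # consecutive features share a latent segment value (segmented CNA)
        for start in range(0, p, block):
            seg = rng.standard_normal(n)
            rows = slice(start, min(start + block, p))
            x[rows] = 0.7 * seg + 0.7 * x[rows]
    elif modules:
        # co-expression modules: ~2/3 of features form groups of 4 sharing
        # a module factor (pairwise rho ~0.64); the rest stay independent
        n_grouped = (2 * p) // 3
        for start in range(0, n_grouped, 4):
            f = rng.standard_normal(n)
            rows = slice(start, min(start + 4, n_grouped))
            x[rows] = 0.8 * f + 0.6 * x[rows]
    lam = float(loading)
    for i in planted_idx:
        x[i] = lam * u + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    if modules and planted_idx:
        # each planted gene gets one co-regulated partner, as co-expressed
        # neighbours of a driver gene would show in real data
        free = [j for j in range(p) if j not in planted_idx]
        partners = rng.choice(len(free), size=min(len(planted_idx), len(free)), replace=False)
        for i, jpos in zip(planted_idx, partners):
            j = free[jpos]
            x[j] = 0.8 * x[i] + 0.6 * rng.standard_normal(n)
    return x


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate one aligned multi-omic cohort. All randomness flows from
    ``config.seed`` through a single named generator."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i:04d}" for i in range(n)]
    u = rng.standard_normal(n)  # shared latent risk factor

    matrices: dict = {}
    planted: dict = {}
    coefs: dict = {}
    eta = np.zeros(n)

    for source in ("EXPR", "MIRNA", "CNA", "MUT"):
        p = config.n_features_per_source.get(source, 0)
        if p == 0:
            continue
        k = config.n_planted.get(source, 0)
        ids = _feature_ids(source, p)
        planted_idx = list(rng.choice(p, size=k, replace=False)) if k else []
        beta = config.coefficients(source)
        if source == "MUT":
            lo, hi = config.mutation_frequency_range
            freq = rng.uniform(lo, hi, size=p)
            x = (rng.random((p, n)) < freq[:, None]).astype(float)
            for j, i in enumerate(planted_idx):
                # mutation probability rises with the latent risk factor
                logit = np.log(freq[i] / (1 - freq[i])) + 1.5 * u
                x[i] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
        else:
            x = _continuous_matrix(
                rng, p, n, planted_idx, config.latent_loading, u,
                block=4 if source == "CNA" else None,
                modules=source in ("EXPR", "MIRNA"),
            )
        for j, i in enumerate(planted_idx):
            eta += beta[j] * x[i]
        matrices[source] = OmicsMatrix(
            source, pd.DataFrame(x, index=ids, columns=patients)
        )
        planted[source] = [ids[i] for i in planted_idx]
        coefs[source] = beta

    eta = eta - eta.mean()
    # Weibull event times: hazard scales with exp(eta)
    e = rng.exponential(size=n)
    t_event = config.baseline_scale * (e / np.exp(eta)) ** (1.0 / config.weibull_shape)
    rate = calibrate_censoring(t_event, config.censoring_target)
    survival, achieved = apply_censoring(patients, t_event, rate, rng)

    network = _make_network(config, rng, planted.get("EXPR", []),
                            matrices["EXPR"].feature_ids if "EXPR" in matrices else [])
    target_map = _make_target_map(config, rng, matrices, planted)

    truth = TruthRecord(planted, coefs, achieved, config.seed)
    return Cohort(survival, matrices, network, target_map, truth)


def apply_censoring(patients, event_times, rate: float, rng):
    """Race exponential censoring (rate 0 = none) against the event times."""
    event_times = np.asarray(event_times, dtype=float)
    if rate > 0:
        c = rng.exponential(scale=1.0 / rate, size=event_times.size)
        time = np.minimum(event_times, c)
        event = (event_times <= c).astype(int)
    else:
        time = event_times.copy()
        event = np.ones(event_times.size, dtype=int)
    achieved = 1.0 - event.mean()
    return SurvivalData(list(patients), time, event), float(achieved)


def _make_network(config, rng, planted_expr, expr_ids) -> InteractionNetwork:
    """Preferential-attachment graph over EXPR gene ids.

    Planted genes are rewired into one connected chain so the network-guided
    selector can in principle recover them; an optional hub node of
    configurable degree supports hub-exclusion behavior.
    """
    p = len(expr_ids)
    if p == 0:
        return InteractionNetwork()
    m = max(1, int(round(config.network_degree_param)))
    g = nx.barabasi_albert_graph(p, min(m, max(1, p - 1)), seed=int(rng.integers(2**31)))
    # shuffle the node->gene assignment so planted genes are not all early hubs
    perm = rng.permutation(p)
    mapping = {i: expr_ids[perm[i]] for i in range(p)}
    g = nx.relabel_nodes(g, mapping)
    for a, b in zip(planted_expr, planted_expr[1:]):
        g.add_edge(a, b)
    if config.hub_degree:
        candidates = [x for x in expr_ids if x not in planted_expr]
        hub = candidates[int(rng.integers(len(candidates)))]
        others = [x for x in expr_ids if x != hub]
        rng.shuffle(others)
        for other in others[: config.hub_degree]:
            g.add_edge(hub, other)
    g.remove_edges_from(nx.selfloop_edges(g))
    return InteractionNetwork(g)


def _make_target_map(config, rng, matrices, planted) -> MirnaTargetMap:
    """Every miRNA targets 1-3 EXPR genes; planted miRNAs also target a
    planted EXPR gene when one exists (shared-pathway realism)."""
    if "MIRNA" not in matrices or "EXPR" not in matrices:
        return MirnaTargetMap({})
    expr_ids = matrices["EXPR"].feature_ids
    targets = {}
    planted_mirna = set(planted.get("MIRNA", []))
    planted_expr = planted.get("EXPR", [])
    for mid in matrices["MIRNA"].feature_ids:
        k = int(rng.integers(1, 4))
        chosen = set(rng.choice(expr_ids, size=min(k, len(expr_ids)), replace=False))
        if mid in planted_mirna and planted_expr:
            chosen.add(planted_expr[int(rng.integers(len(planted_expr)))])
        targets[mid] = chosen
    return MirnaTargetMap(targets)


def write_dataset(cohort: Cohort, directory) -> list:
    """Write the cohort as plain TSV files; returns the paths written.

    Emits one matrix file per source, the clinical table, the network and
    miRNA-target edge lists, and the truth record as a flat key-value file.
    """
    d = ensure_dir(directory)
    paths = []
    for source, matrix in cohort.matrices.items():
        path = d / f"{source.lower()}.tsv"
        write_matrix(matrix, path)
        paths.append(path)
    clinical = d / "clinical.tsv"
    write_clinical(cohort.survival, clinical)
    paths.append(clinical)
    net = d / "network.tsv"
    write_edge_list(cohort.network, net)
    paths.append(net)
    tmap = d / "mirna_targets.tsv"
    write_target_map(cohort.target_map, tmap)
    paths.append(tmap)
    truth_path = d / "truth.txt"
    with open(truth_path, "w") as fh:
        fh.write(f"seed\t{cohort.truth.seed}\n")
        fh.write(f"achieved_censoring\t{cohort.truth.achieved_censoring:.6f}\n")
        for source, ids in cohort.truth.planted.items():
            fh.write(f"planted_{source}\t{','.join(ids)}\n")
            coefs = ",".join(f"{c:.6g}" for c in cohort.truth.coefficients[source])
            fh.write(f"coefficients_{source}\t{coefs}\n")
    return paths
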