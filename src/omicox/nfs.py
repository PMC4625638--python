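"""Network-guided forward growth of Cox models.

Every feature starts as a single-feature model scored by its univariate
Cox p-value.  Each generation, every surviving model is expanded by one
eligible network neighbor at a time (neighbor of any member, not already
in the model, node degree within the hub limit, present in the data);
candidates are deduplicated, scored by the likelihood-ratio p-value of
the multivariate fit, and the top fraction survives to grow again.  The
best-scoring model observed at any generation is returned, refit on the
training data.

For miRNA data the gene network is converted to a surrogate network in
which each miRNA inherits the edges of the genes it targets.  On MERGE
data, gene edges apply to any source's feature carrying that gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import InteractionNetwork, MirnaTargetMap, SurvivalData, ValidationError
from .metabase import gene_of
from .survival import FitError, SurvivalModel, fit_cox


@dataclass
class NFSConfig:
    top_fraction: float = 0.05
    max_iterations: int = 10
    hub_degree_limit: int = 1000
    max_models: int | None = 100  # beam cap on survivors per generation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValidationError("top_fraction must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.max_models is not None and self.max_models < 1:
            raise ValidationError("max_models must be >= 1 or None")


@dataclass(frozen=True)
class CandidateModel:
    features: frozenset
    score: float  # model-level p-value; smaller is better
    parent: frozenset | None = None


def build_surrogate_network(
    ppi: InteractionNetwork, targets: MirnaTargetMap
) -> InteractionNetwork:
    """Each miRNA inherits the edges of every gene it targets.

    Gene-gene edges are retained; a miRNA whose targets have no edges
    becomes an isolated node; no self-loops are introduced.
    """
    g = ppi.graph.copy()
    for mirna, genes in targets.items():
        g.add_node(mirna)
        for gene in genes:
            for neighbor in ppi.neighbors(gene):
                if neighbor != mirna:
                    g.add_edge(mirna, neighbor)
    return InteractionNetwork(g)


def univariate_screen(X, survival: SurvivalData) -> dict:
    """Wald p-value of a univariate Cox fit per feature; failures get p=1."""
    df = X.df.T
    pvals = {}
    for fid in df.columns:
        col = df[[fid]].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            pvals[fid] = 1.0
            continue
        try:
            fit = fit_cox(col, survival, feature_ids=[fid])
            p = float(fit.wald_p[0])
            pvals[fid] = p if np.isfinite(p) and fit.converged else 1.0
        except FitError:
            pvals[fid] = 1.0
    return pvals


def _score_model(features, df, survival) -> float:
    fit = fit_cox(df[list(features)], survival)
    if not fit.converged:
        raise FitError("model fit did not converge")
    return fit.lrt_p


def _eligible_neighbors(features, network, node_of, available, hub_limit):
    nodes_in_model = {node_of(f) for f in features}
    out = set()
    for f in features:
        # hub genes are not allowed to grow: neither expanded through
        # nor added as neighbors
        if network.degree(node_of(f)) > hub_limit:
            continue
        for neighbor in network.neighbors(node_of(f)):
            if neighbor in nodes_in_model:
                continue
            if network.degree(neighbor) > hub_limit:
                continue
            out.update(available.get(neighbor, ()))
    return out - set(features)


def grow_models(current, network: InteractionNetwork, X, survival: SurvivalData,
                config: NFSConfig):
    """One generation of single-neighbor expansions with a global top cut."""
    df = X.df.T
    available: dict = {}
    for fid in df.columns:
        available.setdefault(gene_of(fid), []).append(fid)
    node_of = gene_of

    seen: set = set()
    candidates: list = []
    for model in current:
        for neighbor_feature in _eligible_neighbors(
            model.features, network, node_of, available, config.hub_degree_limit
        ):
            features = model.features | {neighbor_feature}
            if features in seen:
                continue
            seen.add(features)
            try:
                score = _score_model(features, df, survival)
            except FitError:
                continue
            candidates.append(CandidateModel(features, score, model.features))
    if not candidates:
        return []
    candidates.sort(key=lambda c: (c.score, tuple(sorted(c.features))))
    n_keep = min(len(candidates), math.ceil(config.top_fraction * len(candidates)))
    if config.max_models is not None:
        # the fractional cut alone lets the beam grow roughly geometrically
        # (survivors x branching x top_fraction > survivors on dense
        # networks); the cap bounds per-generation work
        n_keep = min(n_keep, config.max_models)
    return candidates[:n_keep]


def run_nfs(X, survival: SurvivalData, network: InteractionNetwork,
            config: NFSConfig | None = None, targets: MirnaTargetMap | None = None,
            sources=None) -> SurvivalModel:
    """Grow Cox models along the network; return the best model observed."""
    config = config or NFSConfig()
    if targets is not None:
        network = build_surrogate_network(network, targets)
    df = X.df.T
    pvals = univariate_screen(X, survival)
    generation = [
        CandidateModel(frozenset([fid]), p) for fid, p in pvals.items()
    ]
    best = min(generation, key=lambda c: (c.score, tuple(sorted(c.features))))
    for _ in range(config.max_iterations - 1):
        generation = grow_models(generation, network, X, survival, config)
        if not generation:
            break
        contender = generation[0]
        if contender.score < best.score:
            best = contender

    chosen = sorted(best.features)
    final = fit_cox(df[chosen], survival)
    return SurvivalModel(
        feature_ids=chosen,
        sources=[X.source_of(f) for f in chosen],
        beta=final.beta,
        selector="NFS",
        fitness=float(best.score),
        fit=final,
        extras={"score_is_pvalue": True},
    )
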