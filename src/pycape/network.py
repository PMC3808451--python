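"""Directed interaction networks: consolidation, adjacency, export.

The final product of the analysis is an asymmetric adjacency matrix with
source markers in rows and target markers plus phenotypes in columns.
Marker-to-marker entries are significant standardized influences (z);
marker-to-phenotype columns carry back-projected significant main effects.
Pairs excluded by the LD filter are tracked in a parallel "untested" mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cross_io import marker_order
from .eigentraits import EigentraitBasis, back_project_effects
from .scans import PairFilterReport, PairScanResult
from .significance import NullDistribution, empirical_p_many

__all__ = [
    "InteractionNetwork",
    "consolidate_main_effects",
    "build_adjacency",
    "export_network",
]


@dataclass
class InteractionNetwork:
    """Asymmetric adjacency of significant directed effects.

    ``weights`` is a DataFrame with source markers as rows and target
    markers followed by phenotype names as columns; entry (i, j) is the
    signed standardized effect of the significant i -> j edge, 0 otherwise.
    ``untested`` is a boolean marker x marker mask of LD-excluded pairs.
    """

    sources: list[str]
    targets: list[str]
    weights: pd.DataFrame
    untested: pd.DataFrame
    phenotypes: list[str]
    metadata: dict = field(default_factory=dict)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for src in self.sources:
            for tgt in self.targets:
                w = self.weights.at[src, tgt]
                if w != 0:
                    kind = ("variant_phenotype" if tgt in self.phenotypes
                            else "variant_variant")
                    rows.append((src, tgt, float(w),
                                 "+" if w > 0 else "-", kind))
        return pd.DataFrame(
            rows, columns=["source", "target", "weight", "sign", "kind"]
        )


def consolidate_main_effects(pairscan: PairScanResult, basis: EigentraitBasis,
                             null: NullDistribution) -> pd.DataFrame:
    """Consolidate per-pair main effects into per-marker phenotype effects.

    A marker's main effect is re-estimated in every pair containing it; for
    each selected ET the most conservative entry — the one with the largest
    empirical p against the variant-phenotype null — is kept, so an effect
    is claimed only if it survives conditioning on every tested partner
    (a partner that fully absorbs it drives the consolidated p up).  The
    chosen per-ET coefficient vector is back-projected to phenotype space;
    the marker-level p is the smallest of its per-ET conservative p's.

    Returns a tidy DataFrame: marker, phenotype, effect, p, tstat (the
    marker-level p and its standardized effect repeated across that
    marker's phenotype rows).
    """
    if len(null) == 0:
        raise RuntimeError("empty variant-phenotype null")
    stats_df = pairscan.main_effect_stats()
    if len(stats_df):
        stats_df = stats_df.assign(
            p=empirical_p_many(stats_df["tstat"].to_numpy(), null)
        )
    phen = basis.phenotype_names
    ets = [e + 1 for e in pairscan.et_indices]
    rows = []
    markers = []
    for pair in pairscan.pairs:
        for m in pair:
            if m not in markers:
                markers.append(m)
    for marker in markers:
        sub = stats_df[stats_df["marker"] == marker]
        if sub.empty:
            continue
        beta_et = np.zeros(len(ets))
        p_ets, t_ets = [], []
        for k, et in enumerate(ets):
            sub_et = sub[sub["et"] == et]
            if sub_et.empty:
                p_ets.append(1.0)
                t_ets.append(0.0)
                continue
            worst = sub_et.loc[sub_et["p"].idxmax()]
            beta_et[k] = worst["coef"]
            p_ets.append(float(worst["p"]))
            t_ets.append(float(worst["tstat"]))
        k_best = int(np.argmin(p_ets))
        p_marker, t_marker = float(p_ets[k_best]), float(t_ets[k_best])
        effects = back_project_effects(beta_et, basis)
        for ph, eff in zip(phen, effects):
            rows.append((marker, ph, float(eff), p_marker, t_marker))
    return pd.DataFrame(
        rows, columns=["marker", "phenotype", "effect", "p", "tstat"])


def build_adjacency(influences, sig: pd.DataFrame, main_effects: pd.DataFrame,
                    filter_report: PairFilterReport, level: float,
                    marker_map: pd.DataFrame, phenotypes: list[str],
                    metadata: dict | None = None) -> InteractionNetwork:
    """Assemble the asymmetric adjacency matrix of significant effects.

    ``sig`` must carry one row per directed edge with columns source,
    target, z, adjusted, significant (as produced by the pipeline from
    :func:`pycape.significance.adjust`); ``main_effects`` must carry
    marker, phenotype, effect, significant.  Rows and marker columns are
    ordered by chromosome then position with covariates (chromosome "0")
    first.
    """
    markers = marker_order(marker_map)
    universe = set(markers)
    bad = ({s for s in sig["source"]} | {t for t in sig["target"]}) - universe
    if bad:
        raise ValueError(f"edges refer to markers outside the map: {sorted(bad)}")
    targets = markers + list(phenotypes)
    W = pd.DataFrame(0.0, index=pd.Index(markers, name="source"),
                     columns=pd.Index(targets, name="target"))
    for row in sig.itertuples(index=False):
        if row.significant and row.source != row.target:
            W.at[row.source, row.target] = row.z
    if len(main_effects):
        for row in main_effects.itertuples(index=False):
            if getattr(row, "significant", False):
                W.at[row.marker, row.phenotype] = row.effect
    untested = pd.DataFrame(False, index=W.index, columns=pd.Index(markers))
    for (a, b) in list(filter_report.excluded_ld) + list(
            filter_report.excluded_other):
        if a in universe and b in universe:
            untested.at[a, b] = untested.at[b, a] = True
            W.at[a, b] = W.at[b, a] = 0.0
    meta = {"level": level}
    meta.update(metadata or {})
    return InteractionNetwork(
        sources=markers, targets=targets, weights=W, untested=untested,
        phenotypes=list(phenotypes), metadata=meta,
    )


def _to_graph(net: InteractionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for m in net.sources:
        g.add_node(m, kind="marker")
    for p in net.phenotypes:
        g.add_node(p, kind="phenotype")
    for row in net.edge_list().itertuples(index=False):
        g.add_edge(row.source, row.target, weight=row.weight,
                   sign=row.sign, kind=row.kind)
    return g


def export_network(net: InteractionNetwork, fmt: str, path) -> None:
    """Serialize a network.

    "adjacency_csv" writes the labelled weight matrix to ``path`` and the
    untested mask next to it (``<path>.mask.csv``); "edge_list" writes one
    row per nonzero edge; "graphml" writes standard GraphML with weight and
    sign edge attributes.
    """
    if fmt == "adjacency_csv":
        net.weights.to_csv(path)
        net.untested.astype(int).to_csv(str(path) + ".mask.csv")
    elif fmt == "edge_list":
        net.edge_list().to_csv(path, index=False)
    elif fmt == "graphml":
        nx.write_graphml(_to_graph(net), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_adjacency_csv(path) -> pd.DataFrame:
    """Re-read a matrix written by export_network(..., "adjacency_csv")."""
    return pd.read_csv(path, index_col=0)
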