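"""Pedigree trees and mother–progeny heteroplasmy correlations.

Tracked time-lapse data give every cell a parent link, so a population
founded by one zygote forms a pedigree tree.  To ask whether mtDNA is
partitioned unequally at division, each cell's h value is sampled at a
matched growth stage — the first frame where its bud has reached 20 %
of the mother volume — and h is correlated (Spearman) across four
relation types per population:

* M–D     mother vs daughter, each at its own matched stage;
* M–GD    mother vs granddaughter;
* M–M_D   mother vs herself at the daughter's sampling time;
* M–M_GD  mother vs herself at the granddaughter's sampling time.

Unequal partitioning predicts Spearman(M, M_D) > Spearman(M, D), with a
further drop from D to GD; a paired t-test across populations compares
relation types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RELATIONS = ("M-D", "M-GD", "M-MD", "M-MGD")


@dataclass
class PedigreeTree:
    """Parent→child pedigree with per-node birth frame."""

    graph: nx.DiGraph
    roots: list

    @property
    def is_forest(self) -> bool:
        return len(self.roots) > 1


def build_tree(records: pd.DataFrame) -> PedigreeTree:
    """Build the pedigree from a cell-record table.

    Expects ``cell_id``, ``parent_id`` (empty/NaN for founders) and
    ``frame`` columns.  Raises on orphaned parent references, multiple
    parents or cycles; multiple roots (a mixed field of view) are
    returned and flagged with a warning.
    """
    g = nx.DiGraph()
    birth = records.groupby("cell_id")["frame"].min()
    parents = records.dropna(subset=["parent_id"]).groupby("cell_id")["parent_id"].unique()
    for cid, frame in birth.items():
        g.add_node(cid, birth_frame=int(frame))
    orphans = []
    for cid, ps in parents.items():
        if len(ps) > 1:
            raise ValueError(f"cell {cid} has multiple parents: {sorted(ps)}")
        p = ps[0]
        if p not in g:
            orphans.append((cid, p))
            continue
        g.add_edge(p, cid)
    if orphans:
        raise ValueError(f"records reference missing parents: {orphans}")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("pedigree contains a cycle")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) > 1:
        logger.warning("pedigree is a forest with %d roots (mixed field of view?)", len(roots))
    return PedigreeTree(g, roots)


def stage_matched_h(cell_id, table: pd.DataFrame, target_ratio: float = 0.2):
    """h at the first frame where the cell's bud reaches the target ratio.

    The match is inclusive at the target and takes the earliest
    qualifying frame; a cell that never buds to the target ratio is
    excluded (returns ``None``) and logged.  ``table`` is an h-value
    table with ``cell_id``, ``frame``, ``bud_ratio`` and ``h`` columns.
    """
    rows = table[(table.cell_id == cell_id) & (table.bud_ratio >= target_ratio)]
    rows = rows.dropna(subset=["h"])
    if rows.empty:
        logger.info("cell %s never reaches bud ratio %.2f; excluded", cell_id, target_ratio)
        return None
    first = rows.loc[rows.frame.idxmin()]
    return float(first.h), int(first.frame)


def _h_at_frame(cell_id, frame, table):
    rows = table[(table.cell_id == cell_id) & (table.frame == frame)].dropna(subset=["h"])
    if rows.empty:
        return None
    return float(rows.h.iloc[0])


def relation_pairs(
    tree: PedigreeTree, table: pd.DataFrame, target_ratio: float = 0.2
) -> pd.DataFrame:
    """All (relation, h_first, h_second) pairs of one population.

    For every mother M with a stage-matched h, each daughter D matched at
    its own 20 % bud stage (at frame t_D) contributes an M–D pair and an
    M–M_D pair (M's own h re-read at t_D); granddaughters contribute
    M–GD and M–M_GD pairs the same way.
    """
    g = tree.graph
    rows = []
    for m in g.nodes:
        hm = stage_matched_h(m, table, target_ratio)
        if hm is None:
            continue
        h_m, _ = hm
        for d in g.successors(m):
            hd = stage_matched_h(d, table, target_ratio)
            if hd is not None:
                h_d, t_d = hd
                rows.append(("M-D", m, d, h_m, h_d))
                h_md = _h_at_frame(m, t_d, table)
                if h_md is not None:
                    rows.append(("M-MD", m, m, h_m, h_md))
            for gd in g.successors(d):
                hgd = stage_matched_h(gd, table, target_ratio)
                if hgd is None:
                    continue
                h_gd, t_gd = hgd
                rows.append(("M-GD", m, gd, h_m, h_gd))
                h_mgd = _h_at_frame(m, t_gd, table)
                if h_mgd is not None:
                    rows.append(("M-MGD", m, m, h_m, h_mgd))
    return pd.DataFrame(rows, columns=["relation", "first_id", "second_id", "h_first", "h_second"])


def relation_correlation(pairs: pd.DataFrame, method: str = "spearman") -> pd.Series:
    """One correlation coefficient per relation type for one population.

    Spearman rank correlation with average ranks for ties (scipy's
    convention); relations with fewer than 3 pairs or a constant vector
    are excluded with a warning.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    out = {}
    for rel, grp in pairs.groupby("relation"):
        if len(grp) < 3:
            logger.warning("relation %s has %d < 3 pairs; excluded", rel, len(grp))
            continue
        if grp.h_first.nunique() == 1 or grp.h_second.nunique() == 1:
            logger.warning("relation %s has a constant vector; correlation undefined", rel)
            continue
        rho = stats.spearmanr(grp.h_first, grp.h_second).statistic
        out[rel] = float(rho)
    return pd.Series(out, name="spearman_rho")


def compare_relations(
    coefficients: pd.DataFrame, relation_a: str, relation_b: str
) -> tuple[float, float]:
    """Two-sided paired t-test of per-population coefficients.

    ``coefficients`` has one row per population and one column per
    relation; populations missing either relation are dropped
    (pairwise-complete).  Returns ``(t, p)``; identical vectors give
    t = 0 and p = 1 by convention (zero-variance difference is flagged).
    """
    for rel in (relation_a, relation_b):
        if rel not in coefficients.columns:
            raise ValueError(f"relation {rel} missing from coefficient table")
    sub = coefficients[[relation_a, relation_b]].dropna()
    if len(sub) < 2:
        raise ValueError("paired t-test needs at least 2 populations with both relations")
    diff = sub[relation_a] - sub[relation_b]
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            logger.warning("identical coefficient vectors; t=0, p=1 by convention")
            return 0.0, 1.0
        logger.warning("constant nonzero difference: t-test degenerate (zero variance)")
        return float(np.inf) * np.sign(diff.iloc[0]), 0.0
    t, p = stats.ttest_rel(sub[relation_a], sub[relation_b])
    return float(t), float(p)


def export_edge_list(tree: PedigreeTree) -> pd.DataFrame:
    """Parent–child edge list with birth frames, for CSV export."""
    rows = [
        {
            "parent_id": u,
            "cell_id": v,
            "birth_frame": tree.graph.nodes[v]["birth_frame"],
        }
        for u, v in tree.graph.edges
    ]
    return pd.DataFrame(rows, columns=["parent_id", "cell_id", "birth_frame"])
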