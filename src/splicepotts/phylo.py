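"""Phylogenetic-signal tests for binary coupling presence/absence traits.

A coupling that is retained by the sparse fit in some species and shrunk to
zero in others defines a binary character on the species tree.  Sankoff
parsimony gives the minimum number of state changes the character requires on
the tree; the Maddison-Slatkin randomization compares that observed score with
scores obtained after permuting the tip states (preserving the number of
present/absent tips).  A small observed score relative to the permutation null
indicates phylogenetic clustering of the trait.  The p-value counts null
scores less than or equal to the observed one, with +1 Monte-Carlo smoothing:
p = (1 + #{null <= obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .model import PottsModel, active_couplings

logger = logging.getLogger(__name__)

_BIG = 1e30


def load_tree(source, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree from a newick path or string."""
    if isinstance(source, dendropy.Tree):
        return source
    text = None
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(source)
    return dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)


@dataclass
class PhyloSignalResult:
    """Maddison-Slatkin outcome for one binary trait."""

    coupling_id: str
    observed_steps: float
    null_min: float
    null_median: float
    null_max: float
    p_raw: float
    n_perm: int
    p_bonferroni: float | None = None
    degenerate: bool = False  # constant trait: test undefined, p_raw = 1


def _tree_topology(tree: dendropy.Tree):
    """Postorder node arrays: leaf label order plus children index lists."""
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    leaves = []
    children = []
    for nd in nodes:
        children.append([index[id(ch)] for ch in nd.child_nodes()])
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("tree contains an unlabelled leaf")
            leaves.append((index[id(nd)], nd.taxon.label))
    labels = [lab for _, lab in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels are not unique")
    return nodes, children, leaves


def _sankoff_batch(
    children: list[list[int]],
    leaves: list[tuple[int, str]],
    states: np.ndarray,
    cost: np.ndarray,
) -> np.ndarray:
    """Vectorized Sankoff DP: states is (batch, n_leaves) of {0,1}."""
    states = np.asarray(states)
    batch = states.shape[0]
    n_nodes = len(children)
    table = np.zeros((n_nodes, batch, 2))
    leaf_pos = {node_idx: col for col, (node_idx, _) in enumerate(leaves)}
    for k in range(n_nodes):
        if not children[k]:
            s = states[:, leaf_pos[k]]
            table[k, :, 0] = np.where(s == 0, 0.0, _BIG)
            table[k, :, 1] = np.where(s == 1, 0.0, _BIG)
        else:
            acc = np.zeros((batch, 2))
            for ch in children[k]:
                cc = table[ch]  # (batch, 2)
                # min over child state t of cost[s, t] + cc[:, t]
                opt0 = np.minimum(cost[0, 0] + cc[:, 0], cost[0, 1] + cc[:, 1])
                opt1 = np.minimum(cost[1, 0] + cc[:, 0], cost[1, 1] + cc[:, 1])
                acc[:, 0] += opt0
                acc[:, 1] += opt1
            table[k] = acc
    return table[n_nodes - 1].min(axis=1)


def sankoff_parsimony(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    cost: np.ndarray | None = None,
) -> float:
    """Minimum substitution cost of a binary character on a rooted tree.

    ``cost`` is the 2x2 substitution-cost matrix (zero diagonal, positive
    off-diagonal; default unit costs, under which the score is the integer
    parsimony step count).  Polytomies are handled natively by the DP.
    """
    if cost is None:
        cost = np.array([[0.0, 1.0], [1.0, 0.0]])
    cost = np.asarray(cost, dtype=float)
    if cost.shape != (2, 2) or cost[0, 0] != 0 or cost[1, 1] != 0:
        raise ValueError("cost must be 2x2 with zero diagonal")
    if cost[0, 1] <= 0 or cost[1, 0] <= 0:
        raise ValueError("off-diagonal costs must be positive")
    _, children, leaves = _tree_topology(tree)
    row = np.empty((1, len(leaves)), dtype=np.int64)
    for col, (_, label) in enumerate(leaves):
        if label not in tip_states:
            raise ValueError(f"missing tip state for leaf {label!r}")
        row[0, col] = int(tip_states[label])
    score = float(_sankoff_batch(children, leaves, row, cost)[0])
    return score


def maddison_slatkin(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    n_perm: int = 10000,
    seed: int = 0,
    coupling_id: str = "",
) -> PhyloSignalResult:
    """Permutation test of phylogenetic clustering for one binary trait.

    Tip states are shuffled uniformly (preserving present/absent counts) and
    Sankoff scores recomputed; p_raw = (1 + #{null <= observed}) / (1 + n_perm).
    A constant trait is reported as degenerate with observed 0 and p_raw 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cost = np.array([[0.0, 1.0], [1.0, 0.0]])
    _, children, leaves = _tree_topology(tree)
    labels = [lab for _, lab in leaves]
    missing = [lab for lab in labels if lab not in tip_states]
    if missing:
        raise ValueError(f"missing tip states for leaves {missing}")
    base = np.array([int(tip_states[lab]) for lab in labels], dtype=np.int64)
    if base.min() == base.max():
        logger.warning("constant trait %s: Maddison-Slatkin undefined", coupling_id)
        return PhyloSignalResult(
            coupling_id, 0.0, 0.0, 0.0, 0.0, 1.0, n_perm, degenerate=True
        )
    observed = float(_sankoff_batch(children, leaves, base[None, :], cost)[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    null = _sankoff_batch(children, leaves, perms, cost)
    p_raw = (1.0 + float(np.sum(null <= observed))) / (1.0 + n_perm)
    return PhyloSignalResult(
        coupling_id,
        observed,
        float(null.min()),
        float(np.median(null)),
        float(null.max()),
        p_raw,
        n_perm,
    )


def bonferroni_adjust(results: list[PhyloSignalResult]) -> list[PhyloSignalResult]:
    """p_bonferroni = min(1, p_raw * m), m = number of tested couplings."""
    if not results:
        raise ValueError("no results to adjust")
    m = len(results)
    return [replace(r, p_bonferroni=min(1.0, r.p_raw * m)) for r in results]


def presence_absence_matrix(models: dict[str, PottsModel]) -> pd.DataFrame:
    """Species x coupling boolean matrix: True where J is exactly nonzero.

    Columns are every coupling active in at least one species, in '-1G:+6T'
    notation, sorted; rows are species labels, sorted.
    """
    per_species = {
        sp: {c.label for c in active_couplings(model)} for sp, model in models.items()
    }
    columns = sorted(set().union(*per_species.values())) if per_species else []
    species = sorted(per_species)
    data = [[lab in per_species[sp] for lab in columns] for sp in species]
    return pd.DataFrame(data, index=species, columns=columns, dtype=bool)


def screen_coupling_signals(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[PhyloSignalResult]:
    """Maddison-Slatkin on every trait column with Bonferroni correction.

    Species absent from the tree are dropped with a warning; tree leaves
    absent from the matrix raise.
    """
    leaf_labels = {
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None
    }
    extra = [sp for sp in traits.index if sp not in leaf_labels]
    if extra:
        logger.warning("dropping species absent from the tree: %s", extra)
        traits = traits.drop(index=extra)
    missing = sorted(leaf_labels - set(traits.index))
    if missing:
        raise ValueError(f"tree leaves missing from the trait matrix: {missing}")
    rng = np.random.default_rng(seed)
    results = []
    for col in traits.columns:
        states = {sp: int(traits.loc[sp, col]) for sp in traits.index}
        results.append(
            maddison_slatkin(
                tree,
                states,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                coupling_id=str(col),
            )
        )
    return bonferroni_adjust(results)


def results_frame(results: list[PhyloSignalResult]) -> pd.DataFrame:
    """Tabular view of Maddison-Slatkin results (TSV-ready)."""
    return pd.DataFrame(
        {
            "coupling": [r.coupling_id for r in results],
            "observed_steps": [r.observed_steps for r in results],
            "null_min": [r.null_min for r in results],
            "null_median": [r.null_median for r in results],
            "null_max": [r.null_max for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "n_perm": [r.n_perm for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
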