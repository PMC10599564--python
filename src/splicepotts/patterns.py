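"""Exonic/intronic consensus classification and coupling-pattern summaries.

Each of the 36 (position, letter) combinations is classified by region (exon
for positions -3..-1, intron for +1..+6) and by consensus status (the most
frequent letter at that position).  Couplings are then averaged per category
pair — e.g. IC-IC for intronic-consensus with intronic-consensus — to expose
the conserved sign structure: stabilizing positive couplings within regions
between consensus bases, and negative exon-intron consensus couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import pandas as pd

from .alphabet import (
    LETTERS,
    N_POSITIONS,
    PAIRS,
    position_label,
    site_base_label,
)
from .marginals import MarginalSet, consensus_sequence
from .model import PottsModel, active_couplings

#: category codes: E/I region x C/N status
CATEGORIES = ("EC", "EN", "IC", "IN")
CATEGORY_PAIRS = tuple(
    f"{a}-{b}" for a, b in combinations_with_replacement(CATEGORIES, 2)
)


@dataclass(frozen=True)
class SiteBaseClass:
    """Region and consensus status of one (position, letter) combination."""

    position: int  # internal index 0..8
    letter: int  # 0..3 (A,C,G,T)
    region: str  # "exon" | "intron"
    status: str  # "consensus" | "non-consensus"

    @property
    def category(self) -> str:
        return ("E" if self.region == "exon" else "I") + (
            "C" if self.status == "consensus" else "N"
        )

    @property
    def label(self) -> str:
        return site_base_label(self.position, self.letter)


def classify_site_bases(m: MarginalSet) -> list[SiteBaseClass]:
    """All 36 site-base classifications from the ensemble's consensus."""
    consensus = consensus_sequence(m)
    out = []
    for i in range(N_POSITIONS):
        region = "exon" if i < 3 else "intron"
        for a in range(4):
            status = "consensus" if LETTERS[a] == consensus[i] else "non-consensus"
            out.append(SiteBaseClass(i, a, region, status))
    return out


def _category_pair_key(c1: str, c2: str) -> str:
    a, b = sorted((c1, c2), key=CATEGORIES.index)
    return f"{a}-{b}"


def group_mean_couplings(
    model: PottsModel,
    classes: list[SiteBaseClass],
    *,
    nonzero_only: bool = False,
) -> pd.DataFrame:
    """Mean coupling per category pair (EC-EC, EC-IN, IC-IC, ...).

    By default the mean runs over every coupling cell in the category pair,
    counting shrunk (exactly zero) couplings; ``nonzero_only`` restricts the
    mean to active couplings.  Also reports the number of cells and of
    nonzero contributors.
    """
    cat = {(c.position, c.letter): c.category for c in classes}
    sums = {k: 0.0 for k in CATEGORY_PAIRS}
    cells = {k: 0 for k in CATEGORY_PAIRS}
    nonzero = {k: 0 for k in CATEGORY_PAIRS}
    nz_sums = {k: 0.0 for k in CATEGORY_PAIRS}
    for p, (i, j) in enumerate(PAIRS):
        for a in range(4):
            for b in range(4):
                key = _category_pair_key(cat[(i, a)], cat[(j, b)])
                v = model.J[p, 4 * a + b]
                sums[key] += v
                cells[key] += 1
                if v != 0.0:
                    nonzero[key] += 1
                    nz_sums[key] += v
    rows = []
    for key in CATEGORY_PAIRS:
        if nonzero_only:
            mean = nz_sums[key] / nonzero[key] if nonzero[key] else 0.0
        else:
            mean = sums[key] / cells[key] if cells[key] else 0.0
        rows.append(
            {
                "category_pair": key,
                "mean_coupling": mean,
                "n_cells": cells[key],
                "n_nonzero": nonzero[key],
            }
        )
    return pd.DataFrame(rows).set_index("category_pair")


def export_couplings(model: PottsModel, m: MarginalSet, prefix) -> tuple[str, str]:
    """Structured circos-style export: 36 site-base nodes with observed
    frequencies, and one edge per active coupling.  Returns the written paths.
    """
    classes = classify_site_bases(m)
    nodes = pd.DataFrame(
        {
            "site_base": [c.label for c in classes],
            "position": [position_label(c.position) for c in classes],
            "letter": [LETTERS[c.letter] for c in classes],
            "region": [c.region for c in classes],
            "status": [c.status for c in classes],
            "frequency": [m.f1[c.position, c.letter] for c in classes],
        }
    )
    acts = active_couplings(model)
    edges = pd.DataFrame(
        {
            "coupling": [c.label for c in acts],
            "site_base_i": [site_base_label(c.i, c.a) for c in acts],
            "site_base_j": [site_base_label(c.j, c.b) for c in acts],
            "J": [c.value for c in acts],
            "sign": [("+" if c.value > 0 else "-") for c in acts],
        }
    )
    nodes_path = f"{prefix}.nodes.tsv"
    edges_path = f"{prefix}.edges.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False, float_format="%.17g")
    edges.to_csv(edges_path, sep="\t", index=False, float_format="%.17g")
    return nodes_path, edges_path


def read_coupling_edges(path) -> dict[str, float]:
    """Read back an edges TSV as {coupling label: J}."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["coupling"], df["J"].astype(float)))
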