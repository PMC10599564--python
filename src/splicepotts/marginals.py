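"""Empirical one- and two-site statistics of donor ensembles.

``f1[i, a]`` is the frequency of letter ``a`` at position ``i`` and
``f2[p, 4*a+b]`` the joint frequency of letters ``(a, b)`` at the unordered
position pair ``p`` (pairs in lexicographic order, ``a`` at the smaller
position).  An optional pseudocount protects downstream maximum-likelihood
fitting from zero cells: alpha counts are added per (position, letter) cell
and alpha/4 per (pair, letter-pair) cell, so both tables share the same
effective denominator N + 4*alpha and remain mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import (
    LETTERS,
    N_LETTER_PAIRS,
    N_LETTERS,
    N_PAIRS,
    N_POSITIONS,
    PAIRS,
    encode_sequences,
    position_label,
)
from .io import DonorEnsemble

logger = logging.getLogger(__name__)


@dataclass
class MarginalSet:
    """One-site (9x4) and two-site (36x16) probability tables."""

    f1: np.ndarray
    f2: np.ndarray
    n_sequences: int | None = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.f1.shape != (N_POSITIONS, N_LETTERS):
            raise ValueError(f"f1 must be 9x4, got {self.f1.shape}")
        if self.f2.shape != (N_PAIRS, N_LETTER_PAIRS):
            raise ValueError(f"f2 must be 36x16, got {self.f2.shape}")

    def validate(self, atol: float = 1e-12) -> None:
        """Check normalization and (pseudocount-free) f2 -> f1 consistency."""
        if not np.allclose(self.f1.sum(axis=1), 1.0, atol=atol):
            raise ValueError("f1 rows do not sum to 1")
        if not np.allclose(self.f2.sum(axis=1), 1.0, atol=atol):
            raise ValueError("f2 pair blocks do not sum to 1")
        if self.pseudocount == 0:
            for p, (i, j) in enumerate(PAIRS):
                block = self.f2[p].reshape(4, 4)
                if not np.allclose(block.sum(axis=1), self.f1[i], atol=atol):
                    raise ValueError(f"f2 pair {p} inconsistent with f1[{i}]")
                if not np.allclose(block.sum(axis=0), self.f1[j], atol=atol):
                    raise ValueError(f"f2 pair {p} inconsistent with f1[{j}]")


def estimate_marginals(ensemble: DonorEnsemble, pseudocount: float = 0.0) -> MarginalSet:
    """Count-based marginal estimate with consistent pseudocount smoothing."""
    if len(ensemble) == 0:
        raise ValueError("cannot estimate marginals from an empty ensemble")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = encode_sequences(ensemble.sequences)
    n = len(ensemble)
    alpha = float(pseudocount)
    f1 = np.empty((N_POSITIONS, N_LETTERS))
    for i in range(N_POSITIONS):
        f1[i] = np.bincount(codes[:, i], minlength=4)
    f1 = (f1 + alpha) / (n + 4 * alpha)
    f2 = np.empty((N_PAIRS, N_LETTER_PAIRS))
    for p, (i, j) in enumerate(PAIRS):
        f2[p] = np.bincount(codes[:, i] * 4 + codes[:, j], minlength=16)
    f2 = (f2 + alpha / 4) / (n + 4 * alpha)
    return MarginalSet(f1, f2, n_sequences=n, pseudocount=alpha)


def consensus_sequence(m: MarginalSet) -> str:
    """Per-position argmax letter; ties go to the alphabetically first letter."""
    out = []
    for i in range(N_POSITIONS):
        row = m.f1[i]
        best = int(np.argmax(row))
        if np.sum(row == row[best]) > 1:
            logger.warning(
                "consensus tie at position %s; keeping %s",
                position_label(i),
                LETTERS[best],
            )
        out.append(LETTERS[best])
    return "".join(out)


def information_content(m: MarginalSet) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_a f log2 f, in [0, 2]."""
    f = m.f1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return 2.0 + terms.sum(axis=1)


def marginals_frame(m: MarginalSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular (f1, f2) views with explicit position labels, for TSV export."""
    f1 = pd.DataFrame(
        m.f1,
        index=[position_label(i) for i in range(N_POSITIONS)],
        columns=list(LETTERS),
    )
    rows = []
    for p, (i, j) in enumerate(PAIRS):
        for a in range(4):
            for b in range(4):
                rows.append(
                    {
                        "pos_i": position_label(i),
                        "pos_j": position_label(j),
                        "letter_i": LETTERS[a],
                        "letter_j": LETTERS[b],
                        "f_ij": m.f2[p, 4 * a + b],
                    }
                )
    return f1, pd.DataFrame(rows)


def export_marginals(m: MarginalSet, prefix) -> None:
    """Write f1, f2 and information content as TSV files ``<prefix>.*.tsv``."""
    f1, f2 = marginals_frame(m)
    f1.to_csv(f"{prefix}.f1.tsv", sep="\t", index_label="position")
    f2.to_csv(f"{prefix}.f2.tsv", sep="\t", index=False)
    ic = pd.Series(
        information_content(m),
        index=[position_label(i) for i in range(N_POSITIONS)],
        name="bits",
    )
    ic.to_csv(f"{prefix}.ic.tsv", sep="\t", index_label="position")
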