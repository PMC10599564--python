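"""Data-driven energy scoring and null ensembles.

Under a fitted model, low energy means frequent donor sequence.  Two null
references calibrate the energy scale: uniformly random 9-mers (the fully
disordered limit) and "decoy" 9-mers read around genomic GT dinucleotides
that are not annotated donors.  Decoys matching no annotated donor sequence
form decoy-A; those whose sequence occurs among annotated donors form
decoy-B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import LETTERS, decode_sequences, revcomp
from .io import DonorEnsemble, GenomeRecord
from .model import PottsModel, energies


@dataclass
class EnergyProfile:
    """Per-sequence energies plus summary statistics."""

    energies: np.ndarray
    mean: float
    sd: float
    quantiles: dict[float, float]

    @classmethod
    def from_energies(cls, e: np.ndarray) -> "EnergyProfile":
        e = np.asarray(e, dtype=float)
        qs = (0.05, 0.25, 0.5, 0.75, 0.95)
        if e.size == 0:
            return cls(e, float("nan"), float("nan"), {q: float("nan") for q in qs})
        return cls(
            energies=e,
            mean=float(e.mean()),
            sd=float(e.std()),
            quantiles={q: float(np.quantile(e, q)) for q in qs},
        )


@dataclass
class DecoySets:
    """Disjoint unique-sequence decoy ensembles around genomic GT loci."""

    decoy_a: DonorEnsemble  # not among annotated donor sequences
    decoy_b: DonorEnsemble  # matches >=1 annotated donor sequence
    n_loci_sampled: int = 0
    n_windows_kept: int = 0


def score_ensemble(model: PottsModel, ensemble: DonorEnsemble) -> EnergyProfile:
    """Energy of every ensemble member plus summary statistics."""
    return EnergyProfile.from_energies(energies(model, ensemble))


def sample_random_sequences(n: int, seed: int) -> DonorEnsemble:
    """n i.i.d. uniform 9-mers over {A,C,G,T}^9."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, 9), dtype=np.uint8)
    return DonorEnsemble(decode_sequences(codes), species_label="random")


def sample_decoys(
    genome: Sequence[GenomeRecord],
    annotated: DonorEnsemble,
    n_loci: int,
    seed: int,
) -> DecoySets:
    """Sample GT loci (both strands, with replacement) and split the unique
    9-mers (3 nt upstream + GT + 4 nt downstream) into decoy-A/decoy-B by
    sequence identity against the annotated donor set."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    # enumerate GT loci as (contig index, strand, offset of the G)
    loci: list[tuple[int, str, int]] = []
    texts = []
    for ci, rec in enumerate(genome):
        fwd = rec.residues
        rev = revcomp(fwd)
        texts.append((fwd, rev))
        for strand, s in (("+", fwd), ("-", rev)):
            start = s.find("GT")
            while start != -1:
                loci.append((ci, strand, start))
                start = s.find("GT", start + 1)
    if not loci:
        raise ValueError("genome contains no GT dinucleotide")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(loci), size=n_loci)
    windows = []
    for k in picks:
        ci, strand, off = loci[k]
        s = texts[ci][0] if strand == "+" else texts[ci][1]
        lo, hi = off - 3, off + 6
        if lo < 0 or hi > len(s):
            continue
        w = s[lo:hi]
        if "N" in w:
            continue
        windows.append(w)
    unique = sorted(set(windows))
    annotated_set = set(annotated.sequences)
    a = [w for w in unique if w not in annotated_set]
    b = [w for w in unique if w in annotated_set]
    return DecoySets(
        decoy_a=DonorEnsemble(a, species_label="decoy-A"),
        decoy_b=DonorEnsemble(b, species_label="decoy-B"),
        n_loci_sampled=n_loci,
        n_windows_kept=len(windows),
    )


def rank_sum_compare(a: EnergyProfile, b: EnergyProfile) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two profiles.

    The p-value comes from scipy's Mann-Whitney U (exact for small untied
    samples, tie-corrected normal approximation otherwise); the reported
    statistic is the tie-corrected normal z, which flips sign when the inputs
    are swapped.
    """
    x = np.asarray(a.energies, dtype=float)
    y = np.asarray(b.energies, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both energy profiles must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    # tie-corrected normal approximation for the signed statistic
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (float(res.statistic) - n1 * n2 / 2.0) / np.sqrt(var) if var > 0 else 0.0
    return {"statistic": float(z), "u": float(res.statistic), "p_value": float(res.pvalue)}


def minimum_energy_sequence(
    model: PottsModel,
    scope: str = "all_states",
    ensemble: DonorEnsemble | None = None,
) -> tuple[str, float]:
    """Argmin of the energy over all 4^9 states or over an ensemble.

    Ties are broken lexicographically (A < C < G < T).
    """
    if scope == "all_states":
        from .model import _logit_grid

        e = -_logit_grid(model.h, model.J).ravel()
        best = int(np.argmin(e))  # first occurrence = lexicographically first
        digits = [(best // 4**k) % 4 for k in range(8, -1, -1)]
        seq = "".join(LETTERS[d] for d in digits)
        return seq, float(e[best])
    if scope == "ensemble":
        if ensemble is None or len(ensemble) == 0:
            raise ValueError("scope='ensemble' requires a non-empty ensemble")
        seqs = sorted(set(ensemble.sequences))
        e = energies(model, seqs)
        best = int(np.argmin(e))
        return seqs[best], float(e[best])
    raise ValueError(f"unknown scope {scope!r}")


def energy_table(profile: EnergyProfile, ensemble: DonorEnsemble) -> pd.DataFrame:
    """Per-sequence energy table for TSV export."""
    return pd.DataFrame(
        {"sequence": ensemble.sequences, "energy": profile.energies}
    )
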