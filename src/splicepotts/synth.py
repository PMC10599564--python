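"""Synthetic fixtures: ground-truth sparse models, planted genomes,
multi-species panels with group-structured couplings, and traits on trees.

Everything here is a pure function of its seed and parameters.  The default
species panel emulates the comparative setting the pipeline targets: a donor-
like field template (consensus CAGGTAAGT with near-deterministic +1G/+2T),
two backbone couplings shared by all species, and one group-specific coupling
per group, with planted magnitudes in the 0.2-0.8 range that a gamma ~ 0.025
L1 fit retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import dendropy
import numpy as np

from .alphabet import LETTERS, N_PAIRS, PAIRS, parse_coupling_label, revcomp
from .io import DonorEnsemble, GenomeRecord
from .model import PottsModel, sample_sequences, zero_sum_gauge

logger = logging.getLogger(__name__)

#: (coupling label, value) lists for the default panel; pattern mirrors the
#: conserved/divergent structure of real donor sites (negative exon-intron
#: consensus couplings, positive within-intron consensus couplings).
DEFAULT_BACKBONE = (("-1G:+5G", -0.5), ("+4A:+5G", 0.5))
DEFAULT_GROUP_COUPLINGS = (
    (("-1G:+6T", -0.7),),
    (("-1G:+4A", -0.7),),
    (("+3G:+5G", 0.7),),
)


def donor_field_template() -> np.ndarray:
    """Donor-like fields favouring the CAGGTAAGT consensus.

    +1G/+2T are near-deterministic (field 4), the remaining consensus letters
    get a moderate bias, echoing the information-content profile of real
    donor sites.  Zero-sum per position.
    """
    consensus = "CAGGTAAGT"
    strong = {3: 4.0, 4: 4.0}  # +1, +2
    h = np.zeros((9, 4))
    for i, c in enumerate(consensus):
        h[i, LETTERS.index(c)] = strong.get(i, 1.2)
    return h - h.mean(axis=1, keepdims=True)


def _couplings_to_J(pairs_values) -> np.ndarray:
    J = np.zeros((N_PAIRS, 16))
    for label, value in pairs_values:
        i, j, a, b = parse_coupling_label(label)
        J[PAIRS.index((i, j)), 4 * a + b] = value
    return J


def make_random_potts(
    seed: int,
    n_couplings: int = 10,
    field_scale: float = 0.5,
    coupling_scale: float = 0.5,
) -> PottsModel:
    """Ground-truth sparse model: normal fields, n random couplings of
    magnitude coupling_scale with random signs."""
    if not 0 <= n_couplings <= 576:
        raise ValueError("n_couplings must be in [0, 576]")
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(9, 4))
    J = np.zeros((N_PAIRS, 16))
    if n_couplings:
        idx = rng.choice(N_PAIRS * 16, size=n_couplings, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_couplings)
        J.flat[idx] = signs * coupling_scale
    return zero_sum_gauge(PottsModel(h, J, gamma=0.0))


def make_planted_genome(
    ensemble: DonorEnsemble,
    seed: int,
    intergenic_length: int = 50,
    contig_id: str = "chr_syn",
) -> tuple[list[GenomeRecord], list[str]]:
    """Toy genome + GFF3 whose exon/intron junctions spell the given 9-mers.

    One two-exon gene per donor sequence, roughly half placed on the minus
    strand; background bases are random A/C/G/T (no N anywhere).  Returns the
    genome records and GFF3 lines (header included).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    rng = np.random.default_rng(seed)

    def random_bases(k: int) -> str:
        return "".join(LETTERS[c] for c in rng.integers(0, 4, size=k))

    chunks = [random_bases(intergenic_length)]
    pos = intergenic_length  # 0-based length so far
    gff = ["##gff-version 3"]
    features = []
    for g, donor in enumerate(ensemble.sequences):
        e1 = int(rng.integers(15, 31))
        il = int(rng.integers(25, 51))
        e2 = int(rng.integers(15, 31))
        exon1 = random_bases(e1 - 3) + donor[:3]
        intron = donor[3:] + random_bases(il - 6)
        exon2 = random_bases(e2)
        gene_seq = exon1 + intron + exon2
        length = len(gene_seq)
        minus = bool(rng.integers(0, 2))
        gstart = pos + 1  # 1-based
        gend = pos + length
        if not minus:
            exons = [(gstart, gstart + e1 - 1), (gstart + e1 + il, gend)]
            strand = "+"
            placed = gene_seq
        else:
            # local coordinate x (1-based) maps to contig gstart + length - x
            exons = [
                (gend - e1 + 1, gend),  # transcript exon 1
                (gstart, gstart + e2 - 1),  # transcript exon 2
            ]
            exons.sort()
            strand = "-"
            placed = revcomp(gene_seq)
        chunks.append(placed)
        chunks.append(random_bases(intergenic_length))
        pos = gend + intergenic_length
        gid, tid = f"gene{g}", f"tx{g}"
        features.append(
            f"{contig_id}\tsynth\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        features.append(
            f"{contig_id}\tsynth\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        for k, (s, e) in enumerate(exons):
            features.append(
                f"{contig_id}\tsynth\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={tid}.exon{k};Parent={tid}"
            )
    gff.extend(features)
    record = GenomeRecord(contig_id, "".join(chunks))
    return [record], gff


def write_gff3(lines: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class PanelDesign:
    """Study design for a multi-species panel with group-structured couplings."""

    n_groups: int = 3
    species_per_group: int = 4
    backbone_couplings: tuple = DEFAULT_BACKBONE
    group_couplings: tuple = DEFAULT_GROUP_COUPLINGS
    field_template: np.ndarray = dc_field(default_factory=donor_field_template)
    n_sequences_per_species: int = 50000
    field_jitter_sd: float = 0.05
    seed: int = 0

    def species_labels(self) -> list[list[str]]:
        return [
            [f"g{g + 1}_s{s + 1}" for s in range(self.species_per_group)]
            for g in range(self.n_groups)
        ]


@dataclass
class SpeciesPanel:
    """A generated panel: ensembles, ground-truth models, groups, group tree."""

    ensembles: dict[str, DonorEnsemble]
    true_models: dict[str, PottsModel]
    group_labels: dict[str, str]
    tree_newick: str


def _group_tree_newick(groups: list[list[str]]) -> str:
    """Ultrametric group tree: multifurcating root (one child per group),
    binary ladders within groups, every leaf at depth 1."""
    clades = []
    for members in groups:
        k = len(members)
        if k == 1:
            clades.append(f"{members[0]}:1")
            continue
        # ladder merge heights rise from 0.25 to the clade root at 0.5
        heights = [
            0.25 + 0.25 * t / (k - 2) if k > 2 else 0.5 for t in range(k - 1)
        ]
        sub, sub_h = f"{members[0]}:{heights[0]:g}", heights[0]
        sub = f"({sub},{members[1]}:{heights[0]:g})"
        for t, sp in enumerate(members[2:], start=1):
            h = heights[t]
            sub = f"({sub}:{h - sub_h:g},{sp}:{h:g})"
            sub_h = h
        clades.append(f"{sub}:{1.0 - sub_h:g}")
    return "(" + ",".join(clades) + ");"


def make_species_panel(design: PanelDesign) -> SpeciesPanel:
    """Sample per-species ensembles from group-structured ground-truth models.

    Every species shares the field template (plus small seeded jitter) and the
    backbone couplings; each group adds its own couplings.  Ensembles are
    exact i.i.d. samples from each species' model.
    """
    if len(design.group_couplings) != design.n_groups:
        raise ValueError("group_couplings must have one entry per group")
    rng = np.random.default_rng(design.seed)
    groups = design.species_labels()
    backbone_J = _couplings_to_J(design.backbone_couplings)
    ensembles: dict[str, DonorEnsemble] = {}
    true_models: dict[str, PottsModel] = {}
    group_labels: dict[str, str] = {}
    for g, members in enumerate(groups):
        group_J = backbone_J + _couplings_to_J(design.group_couplings[g])
        for sp in members:
            h = design.field_template + rng.normal(0, design.field_jitter_sd, (9, 4))
            model = zero_sum_gauge(PottsModel(h, group_J.copy(), gamma=0.0))
            true_models[sp] = model
            group_labels[sp] = f"g{g + 1}"
            ensembles[sp] = sample_sequences(
                model,
                design.n_sequences_per_species,
                seed=int(rng.integers(2**31 - 1)),
                species_label=sp,
            )
    return SpeciesPanel(ensembles, true_models, group_labels, _group_tree_newick(groups))


def make_random_tree(n_leaves: int, seed: int, labels: list[str] | None = None) -> str:
    """Random ultrametric binary tree (coalescent-style pairwise joins).

    Returns newick text; leaf labels default to t1..tn.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [f"t{k + 1}" for k in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")
    rng = np.random.default_rng(seed)
    nodes = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0 / len(nodes)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"


def make_trait_on_tree(
    tree: dendropy.Tree,
    mode: str,
    n_present: int,
    seed: int,
) -> dict[str, int]:
    """Binary tip states, clustered within a clade or uniformly random.

    clustered: presence fills the clade whose size is closest to n_present
    (seeded choice among equals; a size mismatch logs a warning).
    random: uniform assignment with exactly n_present present tips.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    n = len(leaves)
    if not 1 <= n_present <= n - 1:
        raise ValueError(f"n_present must be in [1, {n - 1}]")
    rng = np.random.default_rng(seed)
    if mode == "random":
        present = set(rng.choice(leaves, size=n_present, replace=False).tolist())
    elif mode == "clustered":
        clades = []
        for nd in tree.preorder_node_iter():
            members = [
                lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
            ]
            if 1 <= len(members) <= n - 1:
                clades.append(members)
        best_gap = min(abs(len(c) - n_present) for c in clades)
        if best_gap > 0:
            logger.warning(
                "no clade of size %d; using nearest size %d",
                n_present,
                n_present + best_gap,
            )
        candidates = [c for c in clades if abs(len(c) - n_present) == best_gap]
        present = set(candidates[int(rng.integers(len(candidates)))])
    else:
        raise ValueError(f"mode must be 'clustered' or 'random', got {mode!r}")
    return {lab: int(lab in present) for lab in leaves}
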