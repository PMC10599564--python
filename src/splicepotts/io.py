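"""Genome / annotation reading and donor-site extraction.

Donor (5' splice-site) sequences are the 9-mers formed by the last three
exonic and first six intronic bases of each intron, read in transcript
(5'->3') orientation; minus-strand donors are reverse-complemented.  Introns
are the gaps between consecutive exons of a transcript.  Pre-extracted
ensembles are plain-text files with one 9-mer per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import revcomp

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset("ACGTN")


@dataclass
class GenomeRecord:
    """A single FASTA entry, uppercased, U mapped to T."""

    sequence_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"genome record {self.sequence_id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"genome record {self.sequence_id!r} contains symbols outside "
                f"A/C/G/T/N: {sorted(bad)}"
            )


@dataclass(frozen=True)
class IntronBoundary:
    """Genomic coordinate bookkeeping for one donor site.

    ``donor_position`` is the 1-based forward-strand coordinate of the first
    intronic base (for minus-strand donors, the intronic base adjacent to the
    exon in transcript orientation).
    """

    sequence_id: str
    donor_position: int
    strand: str
    source_feature: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class DonorEnsemble:
    """Multiset of 9-nt donor sequences with provenance.

    ``boundaries`` is parallel to ``sequences`` when the ensemble came from a
    genome extraction; otherwise None.
    """

    sequences: list[str]
    species_label: str = ""
    gt_restricted: bool = False
    boundaries: list[IntronBoundary] | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


def read_genome(path) -> list[GenomeRecord]:
    """Read a (possibly wrapped, multi-record) FASTA file.

    Lowercase input is uppercased and U is mapped to T.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                text_head = line
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
        if not text_head.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(rec.id, residues))
    if not records:
        raise ValueError(f"{path}: no FASTA records parsed")
    return records


def write_genome(records: Iterable[GenomeRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips through read_genome)."""
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.sequence_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _exon_parent(feature) -> str:
    attrs = feature.attributes
    if "Parent" in attrs:
        return attrs["Parent"][0]
    if "transcript_id" in attrs:
        return attrs["transcript_id"][0]
    raise ValueError(
        f"exon at {feature.seqid}:{feature.start}-{feature.end} has neither "
        "Parent= nor transcript_id attribute"
    )


def extract_donor_sites(
    genome: Sequence[GenomeRecord],
    annotation,
    *,
    dedupe: bool = True,
    drop_ambiguous: bool = True,
    species_label: str = "",
) -> DonorEnsemble:
    """Extract the 9-nt donor ensemble from a genome and its GTF/GFF3 annotation.

    For each intron (gap between consecutive exons of a transcript, in
    transcript order) the 9-mer of the last 3 exonic + first 6 intronic bases
    is emitted in transcript orientation; minus-strand donors are
    reverse-complemented.  Windows truncated by a contig edge are always
    dropped (counted in the log); N-containing windows are dropped when
    ``drop_ambiguous``.  With ``dedupe``, one donor is kept per unique
    (sequence_id, donor_position, strand) regardless of how many transcripts
    share it.
    """
    contigs = {rec.sequence_id: rec.residues for rec in genome}
    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        transcripts.setdefault(_exon_parent(exon), []).append(exon)

    sequences: list[str] = []
    boundaries: list[IntronBoundary] = []
    seen: set[tuple[str, int, str]] = set()
    n_truncated = 0
    n_ambiguous = 0

    for tid in sorted(transcripts):
        exons = sorted(transcripts[tid], key=lambda e: e.start)
        if len(exons) < 2:
            continue
        seqid = exons[0].seqid
        strand = exons[0].strand
        if seqid not in contigs:
            raise ValueError(f"transcript {tid}: unknown sequence {seqid!r}")
        contig = contigs[seqid]
        for exon in exons:
            if exon.end > len(contig) or exon.start < 1:
                raise ValueError(
                    f"exon {seqid}:{exon.start}-{exon.end} of transcript {tid} "
                    f"exceeds contig bounds (length {len(contig)})"
                )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end + 1:
                continue  # abutting or overlapping exons: no intron
            if strand == "+":
                # window: 3 exonic (prev.end-2..prev.end) + 6 intronic
                lo = prev.end - 3  # 0-based inclusive
                hi = prev.end + 6  # 0-based exclusive
                donor_pos = prev.end + 1
            else:
                # transcript runs right-to-left; donor exon is `nxt`
                lo = nxt.start - 7
                hi = nxt.start + 2
                donor_pos = nxt.start - 1
            if lo < 0 or hi > len(contig):
                n_truncated += 1
                continue
            window = contig[lo:hi]
            if strand == "-":
                window = revcomp(window)
            if "N" in window:
                n_ambiguous += 1
                if drop_ambiguous:
                    continue
            key = (seqid, donor_pos, strand)
            if dedupe:
                if key in seen:
                    continue
                seen.add(key)
            sequences.append(window)
            boundaries.append(IntronBoundary(seqid, donor_pos, strand, tid))

    if n_truncated:
        logger.warning("dropped %d donor windows truncated at contig edges", n_truncated)
    if n_ambiguous and drop_ambiguous:
        logger.warning("dropped %d donor windows containing N", n_ambiguous)
    return DonorEnsemble(sequences, species_label=species_label, boundaries=boundaries)


def restrict_gt(ensemble: DonorEnsemble) -> DonorEnsemble:
    """Keep exactly the donors with the canonical GT intron start (+1G, +2T)."""
    keep = [k for k, s in enumerate(ensemble.sequences) if s[3:5] == "GT"]
    boundaries = (
        [ensemble.boundaries[k] for k in keep] if ensemble.boundaries else None
    )
    return DonorEnsemble(
        [ensemble.sequences[k] for k in keep],
        species_label=ensemble.species_label,
        gt_restricted=True,
        boundaries=boundaries,
    )


def read_ensemble(path, species_label: str = "") -> DonorEnsemble:
    """Read a plain-text ensemble, one 9-mer over {A,C,G,T} per line."""
    sequences = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            seq = line.strip()
            if not seq:
                continue
            if len(seq) != 9 or any(c not in "ACGT" for c in seq):
                raise ValueError(
                    f"{path}: line {lineno}: expected a 9-mer over A/C/G/T, "
                    f"got {seq!r}"
                )
            sequences.append(seq)
    return DonorEnsemble(sequences, species_label=species_label)


def write_ensemble(ensemble: DonorEnsemble, path) -> None:
    """Write one 9-mer per line (order preserving)."""
    with open(path, "w") as fh:
        for seq in ensemble.sequences:
            fh.write(seq + "\n")
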