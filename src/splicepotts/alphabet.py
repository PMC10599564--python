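"""Shared conventions for the 9-position donor-site alphabet.

A donor (5' splice site) sequence is the 9-mer spanning the exon-intron
boundary: the last three exonic bases (positions -3, -2, -1) followed by the
first six intronic bases (+1..+6).  Letters are ordered A, C, G, T everywhere;
positions are indexed 0..8 internally and labelled -3..-1, +1..+6 externally.
Unordered position pairs are enumerated lexicographically, letter pairs within
a pair block as 4*a + b with a the letter at the smaller position.
"""

from __future__ import annotations

import numpy as np

LETTERS = "ACGT"
N_LETTERS = 4
N_POSITIONS = 9
N_STATES = 4**9  # 262144
POSITIONS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)

#: unordered position pairs (i < j), lexicographic — 36 pairs
PAIRS = tuple((i, j) for i in range(N_POSITIONS) for j in range(i + 1, N_POSITIONS))
PAIR_INDEX = {pair: k for k, pair in enumerate(PAIRS)}
N_PAIRS = len(PAIRS)  # 36
N_LETTER_PAIRS = 16

_LETTER_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _k, _c in enumerate(LETTERS):
    _LETTER_TO_CODE[ord(_c)] = _k

_POSITION_TO_INDEX = {p: i for i, p in enumerate(POSITIONS)}


def position_label(index: int) -> str:
    """Field-style label ('-3'..'+6') for internal position index 0..8."""
    return f"{POSITIONS[index]:+d}"


def site_base_label(index: int, letter: int) -> str:
    """Label such as '-1G' or '+6T' for a (position, letter) combination."""
    return f"{POSITIONS[index]:+d}{LETTERS[letter]}"


def coupling_label(i: int, j: int, a: int, b: int) -> str:
    """Label such as '-1G:+6T' for the coupling J_ij(a, b)."""
    return f"{site_base_label(i, a)}:{site_base_label(j, b)}"


def parse_coupling_label(label: str) -> tuple[int, int, int, int]:
    """Invert :func:`coupling_label`. Returns (i, j, a, b) internal indices."""
    try:
        left, right = label.split(":")
        i = _POSITION_TO_INDEX[int(left[:-1])]
        a = LETTERS.index(left[-1])
        j = _POSITION_TO_INDEX[int(right[:-1])]
        b = LETTERS.index(right[-1])
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed coupling label {label!r}") from exc
    if i >= j:
        raise ValueError(f"coupling label {label!r} must order positions i < j")
    return i, j, a, b


def encode_sequences(seqs) -> np.ndarray:
    """Encode an iterable of 9-mers over {A,C,G,T} as an (n, 9) uint8 array."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, N_POSITIONS), dtype=np.uint8)
    joined = "".join(seqs)
    if len(joined) != N_POSITIONS * len(seqs):
        bad = next(k for k, s in enumerate(seqs) if len(s) != N_POSITIONS)
        raise ValueError(
            f"sequence {bad} has length {len(seqs[bad])}, expected {N_POSITIONS}"
        )
    codes = _LETTER_TO_CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        flat = int(np.argmax(codes > 3))
        raise ValueError(
            f"sequence {flat // N_POSITIONS} contains a non-ACGT symbol "
            f"{joined[flat]!r} at donor position {position_label(flat % N_POSITIONS)}"
        )
    return codes.reshape(len(seqs), N_POSITIONS)


def decode_sequences(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    letters = np.frombuffer(LETTERS.encode("ascii"), dtype=np.uint8)
    flat = letters[np.asarray(codes, dtype=np.uint8).reshape(-1, N_POSITIONS)]
    text = flat.tobytes().decode("ascii")
    return [text[k : k + N_POSITIONS] for k in range(0, len(text), N_POSITIONS)]


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
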