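"""DNA alphabet, IUPAC codes and integer encodings.

The alphabet order A, C, G, T is fixed; all matrix row/column indices in
the package are derived from it.  ``N`` (and any other ambiguity code in
read data) is encoded as 4 so that vectorized kernels can mask it out.
"""

from __future__ import annotations

import numpy as np

#: Ordered DNA alphabet.  Index of a base in this string is its integer code.
ALPHABET = "ACGT"

#: Integer code used for unknown / ambiguous bases inside reads.
N_CODE = 4

#: complement of base code i (A<->T, C<->G); N maps to itself.
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: dinucleotide labels in row order of the 16 x L serialization (AA..TT).
DINUC_LABELS = [a + b for a in ALPHABET for b in ALPHABET]

#: IUPAC nucleotide codes mapped to the set of base codes they allow.
IUPAC = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3),
}

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

#: reverse complement of a dinucleotide code: code(a,b) -> code(comp b, comp a)
RC_DINUC = np.array(
    [COMPLEMENT[c % 4] * 4 + COMPLEMENT[c // 4] for c in range(16)],
    dtype=np.intp,
)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_reads(reads) -> np.ndarray:
    """Encode a collection of reads into an (n, Lmax) uint8 matrix.

    Shorter reads are right-padded with the N code; vectorized kernels
    treat padding exactly like an ambiguous base (no placement may cover
    it, and it contributes nothing to background counts).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    lmax = max(len(r) for r in reads)
    out = np.full((len(reads), lmax), N_CODE, dtype=np.uint8)
    for i, r in enumerate(reads):
        out[i, : len(r)] = encode(r)
    return out


def decode(codes: np.ndarray) -> str:
    """Decode integer codes back to a DNA string (4 -> N)."""
    return "".join("ACGTN"[int(c)] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps N)."""
    return decode(COMPLEMENT[encode(seq)][::-1])


def validate_iupac(seed: str) -> None:
    """Raise ValueError naming position and character for invalid codes."""
    for pos, ch in enumerate(seed.upper()):
        if ch not in IUPAC:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {pos + 1} "
                f"in seed {seed!r}"
            )
    if len(seed) < 2:
        raise ValueError(f"seed must have length >= 2, got {len(seed)}")
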