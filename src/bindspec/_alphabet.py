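"""DNA alphabet utilities shared across the package.

Bases are encoded as integers A=0, C=1, G=2, T=3 throughout; any other
character encodes to -1 and is treated as unscorable.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degenerate nucleotide codes -> set of compatible bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; non-ACGT characters become -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    buf = "".join(seqs)
    return encode(buf).reshape(len(seqs), lengths.pop())


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c >= 0 else "N" for c in np.asarray(codes).ravel())


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement encoded sequences along the last axis.

    In the A=0..T=3 encoding complementation is ``3 - code``; -1 stays
    invalid because the result is clipped back to -1.
    """
    codes = np.asarray(codes)
    out = 3 - codes[..., ::-1]
    out[codes[..., ::-1] < 0] = -1
    return out


def iupac_matrix(pattern: str) -> np.ndarray:
    """(L, 4) boolean matrix: entry [i, b] is True when base b matches
    the degenerate code at position i."""
    mat = np.zeros((len(pattern), 4), dtype=bool)
    for i, sym in enumerate(pattern.upper()):
        try:
            allowed = IUPAC[sym]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {sym!r} at position {i}") from None
        for b in allowed:
            mat[i, BASE_INDEX[b]] = True
    return mat
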