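"""Encoding of IUPAC nucleotide strings as base-probability matrices.

The classifier consumes a ``(width, 4)`` matrix per read: each encoded
position holds a probability distribution over the four canonical bases,
with the column order fixed as **(A, C, G, T)**.  A canonical base is
one-hot (``'A' -> [1, 0, 0, 0]``); an ambiguity code spreads its mass
uniformly over the compatible bases (``'W' -> [0.5, 0, 0, 0.5]``,
``'N' -> [0.25, 0.25, 0.25, 0.25]``).  Zero-padding rows (all-zero) are
distinct from ``N``: absent signal carries no probability mass, an
ambiguous base carries uniform mass.

All functions are pure; lowercase input is accepted and treated as
uppercase, and ``U`` is treated as ``T``.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

__all__ = [
    "BASES",
    "IUPAC_CODES",
    "encode",
    "encode_batch",
    "reverse_complement",
    "shape_to_width",
]

#: Canonical base order of the encoding columns.
BASES = "ACGT"

#: Map from IUPAC code to the set of compatible canonical bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# 256-entry lookup table for vectorized encoding; invalid bytes -> NaN row.
_LUT = np.full((256, 4), np.nan)
for _code, _bases in IUPAC_CODES.items():
    _row = np.zeros(4)
    for _b in _bases:
        _row[BASES.index(_b)] = 1.0 / len(_bases)
    _LUT[ord(_code)] = _row
    _LUT[ord(_code.lower())] = _row

# IUPAC complement (complement of the compatible base set), both cases.
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNTGCAAYRSWMKVHDBN",
)


def _to_bytes(seq: str) -> np.ndarray:
    try:
        raw = seq.encode("ascii")
    except UnicodeEncodeError as exc:  # pragma: no cover - exotic input
        raise ValueError(
            f"non-IUPAC character {seq[exc.start]!r} at position {exc.start}"
        ) from None
    return np.frombuffer(raw, dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a ``(len(seq), 4)`` probability matrix.

    Parameters
    ----------
    seq:
        Non-empty string of IUPAC nucleotide codes (case-insensitive).

    Returns
    -------
    numpy.ndarray
        Matrix whose row *i* is the uniform distribution over the canonical
        bases compatible with ``seq[i]``; every row sums to 1.

    Raises
    ------
    ValueError
        If the string is empty or contains a non-IUPAC character (the
        offending position is reported).
    """
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    mat = _LUT[_to_bytes(seq)]
    bad = np.isnan(mat[:, 0])
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"non-IUPAC character {seq[i]!r} at position {i}")
    return mat


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (ambiguity codes included).

    ``N -> N``, ``W -> W``, ``S -> S``; output is uppercase.  An involution
    on the uppercase IUPAC alphabet (``U`` maps into ``A``/``T`` space).
    """
    mat = _LUT[_to_bytes(seq)]
    bad = np.isnan(mat[:, 0]) if mat.size else np.array([], bool)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"non-IUPAC character {seq[i]!r} at position {i}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def shape_to_width(enc: np.ndarray, width: int = 150) -> np.ndarray:
    """Zero-pad (3' end) or truncate an encoded matrix to exactly ``width`` rows.

    Reads are left-anchored at the tag, so shorter inputs get all-zero rows
    appended and longer inputs keep their first ``width`` rows.  Idempotent
    at the target width; total (never raises on valid matrices).
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    enc = np.asarray(enc, dtype=float)
    n = enc.shape[0]
    if n >= width:
        return enc[:width].copy()
    out = np.zeros((width, enc.shape[1]), dtype=enc.dtype)
    out[:n] = enc
    return out


def encode_batch(
    seqs: Sequence[str],
    width: int = 150,
    on_error: str = "raise",
) -> tuple[np.ndarray, np.ndarray]:
    """Encode and width-shape a batch of reads into an ``(N, width, 4)`` array.

    Parameters
    ----------
    seqs:
        Read sequences (IUPAC strings, possibly of unequal length).
    width:
        Model input width; see :func:`shape_to_width`.
    on_error:
        ``"raise"`` to reject the first invalid read, ``"skip"`` to leave
        invalid reads as all-NaN slices and report their indices.

    Returns
    -------
    (X, bad) :
        ``X`` of shape ``(len(seqs), width, 4)`` and the (possibly empty)
        array of indices of invalid reads.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"unknown on_error mode {on_error!r}")
    n = len(seqs)
    X = np.zeros((n, width, 4))
    bad: list[int] = []
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1 and n > 0 and lengths == {width}:
        # fast path: equal-length reads encoded in one table lookup
        try:
            raw = ("".join(seqs)).encode("ascii")
            mat = _LUT[np.frombuffer(raw, dtype=np.uint8)].reshape(n, width, 4)
        except UnicodeEncodeError:
            mat = None
        if mat is not None:
            nan_rows = np.isnan(mat[:, :, 0]).any(axis=1)
            if not nan_rows.any():
                return mat, np.array([], dtype=int)
            X = mat
            for i in np.flatnonzero(nan_rows):
                if on_error == "raise":
                    encode(seqs[i])  # raises with position information
                X[i] = np.nan
                bad.append(int(i))
            return X, np.asarray(bad, dtype=int)
    for i, s in enumerate(seqs):
        try:
            X[i] = shape_to_width(encode(s), width)
        except ValueError:
            if on_error == "raise":
                raise
            X[i] = np.nan
            bad.append(i)
    return X, np.asarray(bad, dtype=int)
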