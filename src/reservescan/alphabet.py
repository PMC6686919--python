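"""Amino-acid alphabet, encodings and background frequency tables."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetically ordered.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of standard residues.
N_RESIDUES: int = len(AMINO_ACIDS)

#: Integer index used for ambiguous / non-standard residues (X, B, Z, U, O, J).
#: Scoring code treats this index as "emit from background" (log-odds 0).
AMBIGUOUS_INDEX: int = N_RESIDUES

#: Residues accepted in input sequences beyond the standard 20.
AMBIGUITY_CODES: str = "XBZUOJ"

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
for _code in AMBIGUITY_CODES:
    _INDEX[_code] = AMBIGUOUS_INDEX

#: Uniform background distribution over the 20 residues.
UNIFORM_BACKGROUND: np.ndarray = np.full(N_RESIDUES, 1.0 / N_RESIDUES)

# Robinson & Robinson (1991) average composition of proteins, in the
# alphabetical residue order above.  Offered as an alternative decoy
# background; the generator default stays uniform.
ROBINSON_BACKGROUND: np.ndarray = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_BACKGROUND /= ROBINSON_BACKGROUND.sum()

BACKGROUNDS = {"uniform": UNIFORM_BACKGROUND, "robinson": ROBINSON_BACKGROUND}


def is_valid_sequence(seq: str) -> bool:
    """True if every character is a standard residue or allowed ambiguity code."""
    return len(seq) > 0 and all(c in _INDEX for c in seq)


def validate_sequence(seq: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending character, if any."""
    if not seq:
        raise ValueError(f"{name} is empty")
    for i, c in enumerate(seq):
        if c not in _INDEX:
            raise ValueError(f"{name} contains invalid residue {c!r} at position {i}")


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int8 indices (ambiguity codes -> {AMBIGUOUS_INDEX})."""
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"invalid residue {exc.args[0]!r}") from exc


def encode_aligned(row: str, gap: str = "-") -> np.ndarray:
    """Encode an aligned (gapped) row as int16 indices with gaps as -1."""
    return np.fromiter(
        ((-1 if c == gap else _INDEX[c]) for c in row), dtype=np.int16, count=len(row)
    )


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode`; ambiguous indices render as ``X``."""
    return "".join(AMINO_ACIDS[i] if i < N_RESIDUES else "X" for i in indices)


def random_protein(length: int, rng: np.random.Generator, background: np.ndarray | None = None) -> str:
    """Sample an i.i.d. protein string from ``background`` (uniform by default)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    idx = rng.choice(N_RESIDUES, size=length, p=bg / bg.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)
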