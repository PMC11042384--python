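"""Sequence featurization for 20-bp protospacers.

Two representations are produced for every guide:

* a 4 x 20 one-hot matrix (rows in fixed base order, columns are
  protospacer positions 1..20 counted from the 5' end, PAM-distal first),
  consumed by the convolutional model;
* a 404-dimensional bag-of-words vector consumed by the gradient-boosting
  model: 80 positional mononucleotide indicators (20 positions x 4 bases),
  304 positional dinucleotide indicators (19 start positions x 16
  dinucleotides, a dinucleotide at position p spanning bases p and p+1),
  4 mononucleotide counts and 16 dinucleotide counts.

The protospacer string is taken as given in the library table; no
reverse-complementing is performed here. Lowercase input is uppercased;
any other character (including N) is rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Fixed row order of the one-hot matrix and base order of BoW features.
BASES = "ACGT"

#: The 16 dinucleotides in lexicographic order.
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

PROTOSPACER_LENGTH = 20

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

#: Required columns of a guide library table.
LIBRARY_COLUMNS = [
    "guide_id",
    "protospacer",
    "chrom",
    "start",
    "end",
    "strand",
    "dhs_id",
    "region_class",
]


class InvalidProtospacerError(ValueError):
    """Raised for a protospacer of wrong length or alphabet."""


def validate_protospacer(sequence: str, guide_id: str | None = None) -> str:
    """Uppercase and validate a protospacer, returning the clean string.

    Raises :class:`InvalidProtospacerError` naming the offending guide and,
    for alphabet violations, the 1-based position of the first bad character.
    """
    label = f" (guide {guide_id!r})" if guide_id is not None else ""
    if not isinstance(sequence, str):
        raise InvalidProtospacerError(f"protospacer must be a string{label}")
    seq = sequence.upper()
    if len(seq) != PROTOSPACER_LENGTH:
        raise InvalidProtospacerError(
            f"protospacer must be {PROTOSPACER_LENGTH} bp, got {len(seq)}{label}"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in _BASE_INDEX:
            raise InvalidProtospacerError(
                f"invalid character {ch!r} at position {pos}{label}; "
                f"allowed alphabet is {BASES}"
            )
    return seq


def one_hot_encode(sequence: str, guide_id: str | None = None) -> np.ndarray:
    """One-hot encode a 20-mer into a 4 x 20 binary matrix.

    Row order is :data:`BASES`; column p carries a single 1 in the row of
    the base at position p. The encoding is invertible via
    :func:`one_hot_decode`.
    """
    seq = validate_protospacer(sequence, guide_id)
    mat = np.zeros((len(BASES), PROTOSPACER_LENGTH), dtype=np.float64)
    for pos, ch in enumerate(seq):
        mat[_BASE_INDEX[ch], pos] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(BASES), PROTOSPACER_LENGTH):
        raise ValueError(f"expected shape (4, 20), got {matrix.shape}")
    col_sums = matrix.sum(axis=0)
    if not np.array_equal(col_sums, np.ones(PROTOSPACER_LENGTH)):
        raise ValueError("matrix is not one-hot: column sums differ from 1")
    return "".join(BASES[i] for i in matrix.argmax(axis=0))


def bow_feature_names() -> list[str]:
    """The fixed 404-feature vocabulary, in storage order.

    Order: 80 positional mononucleotides (position-major, bases in
    :data:`BASES` order), 304 positional dinucleotides (position-major,
    dinucleotides lexicographic), 4 mononucleotide counts, 16 dinucleotide
    counts. Positions are 1-based from the 5' end.
    """
    names: list[str] = []
    for p in range(1, PROTOSPACER_LENGTH + 1):
        for b in BASES:
            names.append(f"position_{p}_{b}")
    for p in range(1, PROTOSPACER_LENGTH):
        for d in DINUCLEOTIDES:
            names.append(f"position_{p}_{d}")
    for b in BASES:
        names.append(f"freq_{b}")
    for d in DINUCLEOTIDES:
        names.append(f"freq_{d}")
    return names


#: Sizes of the four BoW blocks, in storage order.
BOW_BLOCK_SIZES = (80, 304, 4, 16)
BOW_DIM = sum(BOW_BLOCK_SIZES)


def bow_tokenize(sequence: str, guide_id: str | None = None) -> np.ndarray:
    """Tokenize a protospacer into the 404-dimensional bag-of-words vector."""
    seq = validate_protospacer(sequence, guide_id)
    vec = np.zeros(BOW_DIM, dtype=np.float64)
    n_pos_mono = BOW_BLOCK_SIZES[0]
    n_pos_di = BOW_BLOCK_SIZES[1]
    freq_mono_off = n_pos_mono + n_pos_di
    freq_di_off = freq_mono_off + BOW_BLOCK_SIZES[2]
    for pos, ch in enumerate(seq):  # pos is 0-based here
        bi = _BASE_INDEX[ch]
        vec[pos * 4 + bi] = 1.0
        vec[freq_mono_off + bi] += 1.0
    for pos in range(PROTOSPACER_LENGTH - 1):
        di = _DINUC_INDEX[seq[pos : pos + 2]]
        vec[n_pos_mono + pos * 16 + di] = 1.0
        vec[freq_di_off + di] += 1.0
    return vec


def featurize_library(
    records: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Featurize every guide in a library table.

    Parameters
    ----------
    records
        DataFrame with at least ``guide_id`` and ``protospacer`` columns.

    Returns
    -------
    one_hot
        Array of shape ``(n, 4, 20)``, ordered as the input.
    bow
        DataFrame indexed by ``guide_id`` with the 404 BoW columns, same
        order as the input.

    Any invalid protospacer aborts the whole call; the error message names
    the offending guide id.
    """
    n = len(records)
    one_hot = np.zeros((n, len(BASES), PROTOSPACER_LENGTH), dtype=np.float64)
    bow = np.zeros((n, BOW_DIM), dtype=np.float64)
    ids = records["guide_id"].astype(str).tolist()
    for i, (gid, seq) in enumerate(zip(ids, records["protospacer"])):
        one_hot[i] = one_hot_encode(seq, guide_id=gid)
        bow[i] = bow_tokenize(seq, guide_id=gid)
    bow_df = pd.DataFrame(bow, columns=bow_feature_names(), index=pd.Index(ids, name="guide_id"))
    return one_hot, bow_df


def read_library_tsv(path) -> pd.DataFrame:
    """Read a guide library table (TSV with :data:`LIBRARY_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "dhs_id": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library table missing columns: {missing}")
    return df


def write_bow_tsv(bow: pd.DataFrame, path) -> None:
    """Write a BoW feature matrix as TSV with a feature-name header row."""
    bow.to_csv(path, sep="\t", index=True)
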