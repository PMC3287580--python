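"""Amino-acid trigram featurization.

Each species' concatenated protein sequence is summarized by the counts of
its overlapping length-3 windows over the 20-letter alphabet, giving a
20^3 = 8000 dimensional composition vector; a dataset becomes the
8000 x n matrix A (trigrams x species) that the SVD stage factorizes.
Counts are raw by default — sequence length is an informative signal here,
not a nuisance — with an optional per-column L1 normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .species_io import AMINO_ACIDS, Dataset, ValidationError

N_TRIGRAMS = 20 ** 3

#: All 8000 trigrams in lexicographic order over "ACDEFGHIKLMNPQRSTVWY".
TRIGRAMS: tuple[str, ...] = tuple("".join(t) for t in product(AMINO_ACIDS, repeat=3))

ROW_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRIGRAMS)}

_AA_CODE = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(AMINO_ACIDS):
    _AA_CODE[ord(_aa)] = _i


@dataclass(frozen=True)
class TrigramMatrix:
    """The 8000 x n trigram count matrix with its row/column labelling."""

    counts: np.ndarray            # (8000, n) int64
    species_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.counts.shape != (N_TRIGRAMS, len(self.species_order)):
            raise ValidationError("counts must be 8000 x n_species")

    @property
    def n_species(self) -> int:
        return len(self.species_order)

    def normalized(self) -> np.ndarray:
        """Per-column L1-normalized copy (zero columns left zero)."""
        sums = self.counts.sum(axis=0, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums


def trigram_vector(sequence: str) -> np.ndarray:
    """Count every overlapping trigram of ``sequence`` (stride 1).

    The result has 8000 entries in lexicographic trigram order and sums to
    max(0, L - 2).  Residues outside the standard alphabet are an error
    reported with their position; cleaning is the reader's job, not ours.
    """
    codes = _AA_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValidationError(
            f"non-standard residue {sequence[pos]!r} at position {pos}"
        )
    vec = np.zeros(N_TRIGRAMS, dtype=np.int64)
    if codes.size < 3:
        return vec
    idx = codes[:-2] * 400 + codes[1:-1] * 20 + codes[2:]
    np.add.at(vec, idx, 1)
    return vec


def build_matrix(dataset: Dataset) -> TrigramMatrix:
    """Stack per-species trigram vectors into the 8000 x n matrix A."""
    cols = [trigram_vector(rec.sequence) for rec in dataset.records]
    counts = np.stack(cols, axis=1)
    return TrigramMatrix(counts, tuple(dataset.species_ids))


def write_mtx(matrix: TrigramMatrix, mtx_path, labels_path=None) -> None:
    """Dump counts as MatrixMarket sparse, with an optional label sidecar TSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csc_matrix

    mmwrite(str(mtx_path), csc_matrix(matrix.counts))
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("# rows: trigrams (lexicographic); columns below\n")
            for sid in matrix.species_order:
                fh.write(sid + "\n")
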