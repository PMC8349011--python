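"""Excised-oligomer statistics.

XR-seq captures the ~26-nt oligomers released by nucleotide excision
repair.  Two summaries characterize them: the read-length distribution
(whose mode identifies the predominant excision product) and the
position-specific nucleotide frequency of the predominant length class,
which exposes the pyrimidine enrichment at positions 19-21 created by the
fixed incision distance 3' of the UV lesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import as_read_frame

logger = logging.getLogger("xrcompare")

BASES = "ACGT"

# byte -> base index lookup (A=0 C=1 G=2 T=3, everything else -1)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class FrequencyMatrix:
    """L x 4 position-specific nucleotide frequencies (columns A, C, G, T).

    Each row sums to one; rows are indexed 0..L-1 internally but reported
    1-based in tabular output, matching how oligomer positions are quoted.
    """

    values: np.ndarray  # shape (L, 4), rows sum to 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 4:
            raise ValueError("frequency matrix must have shape (L, 4)")
        if (v < 0).any():
            raise ValueError("frequencies must be >= 0")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each frequency-matrix row must sum to 1")
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @classmethod
    def uniform(cls, L: int) -> "FrequencyMatrix":
        return cls(np.full((L, 4), 0.25))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.L + 1))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FrequencyMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(BASES)].to_numpy(dtype=float))


def length_distribution(reads) -> dict[int, int]:
    """Count reads per exact length (end - start); absent lengths omitted."""
    frame = as_read_frame(reads)
    if len(frame) == 0:
        return {}
    lengths = (frame["end"].to_numpy() - frame["start"].to_numpy()).astype(int)
    vals, counts = np.unique(lengths, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def length_distribution_frame(reads) -> pd.DataFrame:
    dist = length_distribution(reads)
    return pd.DataFrame(
        {"length": sorted(dist), "count": [dist[k] for k in sorted(dist)]}
    )


def encode_sequences(sequences, L: int) -> np.ndarray:
    """Pack equal-length upper-case sequences into an (n, L) base-index
    matrix; rows containing non-ACGT characters get -1 entries."""
    joined = "".join(sequences).encode("ascii")
    arr = np.frombuffer(joined, dtype=np.uint8).reshape(-1, L)
    return _CODE[arr]


def nucleotide_frequency(sequences, L: int = 26) -> FrequencyMatrix:
    """Per-position nucleotide frequency of the length-``L`` class.

    Sequences of a different length or containing non-ACGT characters are
    excluded (their count is logged); an empty surviving set is an error.
    """
    sequences = list(sequences)
    seqs = [s.upper() for s in sequences if len(s) == L]
    skipped_len = len(sequences) - len(seqs)
    if seqs:
        codes = encode_sequences(seqs, L)
        valid = (codes >= 0).all(axis=1)
        n_bad = int((~valid).sum())
        codes = codes[valid]
    else:
        codes = np.empty((0, L), dtype=np.int8)
        n_bad = 0
    if skipped_len or n_bad:
        logger.info(
            "nucleotide_frequency: excluded %d off-length and %d non-ACGT sequences",
            skipped_len, n_bad,
        )
    if codes.shape[0] == 0:
        raise ValueError(f"no valid length-{L} ACGT sequences to count")
    f = np.empty((L, 4))
    for b in range(4):
        f[:, b] = (codes == b).mean(axis=0)
    return FrequencyMatrix(f)
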