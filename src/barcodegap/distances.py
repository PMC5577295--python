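"""Kimura 2-parameter distances with explicit undefined-entry handling.

The K2P model corrects observed divergence using separate transition and
transversion proportions. For an aligned pair, sites where either sequence
carries a gap or an ambiguity code are excluded (pairwise deletion); over
the remaining ``n`` comparable sites with transition proportion ``P`` and
transversion proportion ``Q``,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q).

The distance is UNDEFINED (stored as NaN) when a logarithm argument is
non-positive or when no comparable sites remain; undefined entries are
propagated, never imputed, and downstream summaries report how many were
skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import AlignedSequenceSet

__all__ = [
    "UNDEFINED",
    "LengthError",
    "k2p_distance",
    "distance_matrix",
    "DistanceMatrix",
    "write_distance_tsv",
    "read_distance_tsv",
    "write_phylip_lower",
]

#: Sentinel for an undefined distance (logarithm argument <= 0 or no sites).
UNDEFINED = float("nan")

# Encoding such that transitions (A<->G, C<->T) are exactly XOR == 1.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "U": 3}
_MISSING = 255


class LengthError(ValueError):
    """Sequences of unequal length passed to a pairwise distance."""


def encode_sequences(aln: AlignedSequenceSet) -> np.ndarray:
    """Encode an alignment as a (n_seqs, n_cols) uint8 matrix.

    A, G, C, T map to 0, 1, 2, 3 (U to 3); gaps and ambiguity codes map to a
    missing sentinel and are excluded from every pairwise comparison.
    """
    out = np.full((len(aln.records), aln.alignment_length), _MISSING, dtype=np.uint8)
    for i, rec in enumerate(aln.records):
        for j, ch in enumerate(rec.residues):
            out[i, j] = _CODE.get(ch, _MISSING)
    return out


def _encode_one(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c.upper(), _MISSING) for c in seq], dtype=np.uint8)


def _k2p_from_counts(n: int, ts: int, tv: int) -> float:
    if n == 0:
        return UNDEFINED
    p = ts / n
    q = tv / n
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(a1) - 0.25 * math.log(a2) + 0.0  # avoid -0.0


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance between two aligned sequences under pairwise deletion.

    Returns ``(distance, comparable_sites)``; distance is NaN when undefined.
    Raises :class:`LengthError` for unequal lengths.
    """
    if len(seq_a) != len(seq_b):
        raise LengthError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a = _encode_one(seq_a)
    b = _encode_one(seq_b)
    mask = (a != _MISSING) & (b != _MISSING)
    n = int(mask.sum())
    diff = mask & (a != b)
    ts = int((diff & ((a ^ b) == 1)).sum())
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(n, ts, tv), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over labelled sequences.

    ``values`` holds NaN for undefined pairs; ``comparable_sites`` counts the
    sites each pair was computed from (0 where no overlap existed).
    """

    labels: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.comparable_sites is None:
            self.comparable_sites = np.zeros((n, n), dtype=int)
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}
        if len(self._index) != n:
            raise ValueError("duplicate labels in distance matrix")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def index_of(self, label: str) -> int:
        return self._index[label]

    def is_defined(self, a: str, b: str) -> bool:
        return not math.isnan(self[a, b])

    @property
    def n_undefined_pairs(self) -> int:
        """Number of undefined unordered off-diagonal pairs."""
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)].copy(),
            self.comparable_sites[np.ix_(idx, idx)].copy(),
        )


def distance_matrix(aln: AlignedSequenceSet) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment (pairwise deletion)."""
    if len(aln.records) < 2:
        raise ValueError("distance matrix requires at least 2 sequences")
    enc = encode_sequences(aln)
    n = enc.shape[0]
    valid = enc != _MISSING
    values = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a = enc[i]
        rest = enc[i + 1:]
        mask = valid[i] & valid[i + 1:]
        counts = mask.sum(axis=1)
        diff = mask & (a[None, :] != rest)
        ts = (diff & ((a[None, :] ^ rest) == 1)).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(counts > 0, ts / np.maximum(counts, 1), np.nan)
            q = np.where(counts > 0, tv / np.maximum(counts, 1), np.nan)
            a1 = 1.0 - 2.0 * p - q
            a2 = 1.0 - 2.0 * q
            d = np.where(
                (a1 > 0) & (a2 > 0),
                -0.5 * np.log(np.where(a1 > 0, a1, 1.0))
                - 0.25 * np.log(np.where(a2 > 0, a2, 1.0)),
                np.nan,
            ) + 0.0  # normalize -0.0 from identical pairs
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        sites[i, i + 1:] = counts
        sites[i + 1:, i] = counts
    np.fill_diagonal(sites, valid.sum(axis=1))
    return DistanceMatrix(list(aln.ids), values, sites)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with id header row/column; undefined entries as ``NA``."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.labels) + "\n")
        for i, lbl in enumerate(dm.labels):
            cells = [
                "NA" if math.isnan(v) else f"{v:.10g}" for v in dm.values[i]
            ]
            fh.write(lbl + "\t" + "\t".join(cells) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        n = len(labels)
        values = np.zeros((n, n), dtype=float)
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            values[i] = [float("nan") if c == "NA" else float(c) for c in parts[1:]]
    return DistanceMatrix(labels, values)


def write_phylip_lower(dm: DistanceMatrix, path: str | Path) -> None:
    """Lower-triangle PHYLIP-style matrix for interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, lbl in enumerate(dm.labels):
            cells = [
                "NA" if math.isnan(v) else f"{v:.6f}" for v in dm.values[i, :i]
            ]
            fh.write("\t".join([lbl] + cells).rstrip("\t") + "\n")
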