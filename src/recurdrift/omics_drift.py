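"""Cosine-dissimilarity drift between matched tumor pairs across omics layers.

For each layer (copy number, transcript, protein) the feature x sample
matrix is reduced to its complete-case rows (any feature with a missing
value in any sample is dropped, so every pairwise comparison uses the same
feature set), and the evolutionary drift of a patient is the cosine
dissimilarity 1 - cos(theta) between the primary-tumor and recurrence
columns.  Cosine dissimilarity is scale-invariant per column, lives in
[0, 2], and is 0 exactly when the two profiles are positive scalar
multiples of each other.

The clustering companion builds the full sample x sample dissimilarity
matrix, runs agglomerative clustering for the dendrogram, and flags a pair
as "co-clustering" when its two members are mutual nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

LAYERS = ("CN", "RNA", "protein")


class DriftError(ValueError):
    pass


@dataclass
class OmicsMatrix:
    """One omics layer as a feature x sample table."""

    layer: str
    data: pd.DataFrame  # features x samples

    def complete_cases(self) -> pd.DataFrame:
        """Rows without any missing value — the basis of every dissimilarity."""
        return self.data.dropna(axis=0, how="any")


@dataclass(frozen=True)
class PairDissimilarity:
    patient_id: str
    layer: str
    value: float


def cosine_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cosine similarity between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise DriftError("inputs must be equal-length non-empty vectors")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DriftError("cosine dissimilarity undefined for a zero vector")
    return float(1.0 - float(np.dot(x, y)) / (nx * ny))


def dissimilarity_matrix(matrix: OmicsMatrix) -> pd.DataFrame:
    """Sample x sample cosine dissimilarities on complete-case features."""
    data = matrix.complete_cases()
    if data.shape[0] == 0:
        raise DriftError(f"no complete-case features in layer {matrix.layer}")
    X = data.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        bad = list(data.columns[norms == 0])
        raise DriftError(f"zero-norm sample column(s): {bad}")
    sim = (X.T @ X) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=data.columns, columns=data.columns)


def pair_dissimilarities(
    matrix: OmicsMatrix, pairs: Mapping[str, tuple[str, str]]
) -> list[PairDissimilarity]:
    """Per-patient drift: cosine dissimilarity between the pair's two columns.

    ``pairs`` maps patient id -> (primary sample, recurrence sample).
    Patients with a missing column are skipped with a warning.
    """
    data = matrix.complete_cases()
    out: list[PairDissimilarity] = []
    for patient, (pt, ibtr) in pairs.items():
        if pt not in data.columns or ibtr not in data.columns:
            import warnings

            warnings.warn(f"patient {patient}: missing pair member, skipped", stacklevel=2)
            continue
        value = cosine_dissimilarity(data[pt].to_numpy(), data[ibtr].to_numpy())
        out.append(PairDissimilarity(patient, matrix.layer, value))
    return out


@dataclass
class CoclusterResult:
    flags: dict[str, bool]  # patient -> pair members are mutual nearest neighbors
    linkage_matrix: np.ndarray
    sample_order: list[str]
    dissimilarities: pd.DataFrame

    @property
    def cocluster_fraction(self) -> float:
        if not self.flags:
            return float("nan")
        return sum(self.flags.values()) / len(self.flags)


def pair_cocluster(
    matrix: OmicsMatrix,
    pairs: Mapping[str, tuple[str, str]],
    method: str = "average",
) -> CoclusterResult:
    """Hierarchical clustering of all samples plus mutual-nearest-neighbor flags.

    A pair co-clusters when each member's nearest other sample (by cosine
    dissimilarity) is its partner — an explicit operationalization of two
    leaves joining first in the dendrogram.
    """
    d = dissimilarity_matrix(matrix)
    if d.shape[0] < 4:
        raise DriftError("co-clustering needs at least 4 samples")
    Z = linkage(squareform(d.to_numpy(), checks=False), method=method)
    arr = d.to_numpy().copy()
    np.fill_diagonal(arr, np.inf)
    nearest = {s: d.columns[i] for s, i in zip(d.columns, np.argmin(arr, axis=1))}
    flags = {}
    for patient, (pt, ibtr) in pairs.items():
        if pt not in d.columns or ibtr not in d.columns:
            continue
        flags[patient] = nearest[pt] == ibtr and nearest[ibtr] == pt
    return CoclusterResult(flags, Z, list(d.columns), d)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        return (
            f"({node(a)}:{heights[i] - heights[a]:.6g},"
            f"{node(b)}:{heights[i] - heights[b]:.6g})"
        )

    for k, row in enumerate(Z):
        heights[n + k] = float(row[2])
    return node(n + len(Z) - 1) + ";"


def load_matrix(path, layer: str) -> OmicsMatrix:
    """Read a feature x sample TSV (feature ids in the first column)."""
    return OmicsMatrix(layer, pd.read_csv(path, sep="\t", index_col=0))
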