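"""Fingerprint similarity and product clustering.

Bound reaction products are compared by Tanimoto similarity of circular
(Morgan) fingerprints, radius 2 and 2048 bits — the de-facto standard
parameters — and organised into an average-linkage dendrogram over the
distance 1 - Tanimoto.  Fingerprint parameters are recorded on the
dendrogram so downstream reports can state them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .chem import ChemParseError

__all__ = ["Dendrogram", "morgan_fingerprints", "tanimoto", "cluster_products"]

FP_RADIUS = 2
FP_NBITS = 2048


def morgan_fingerprints(
    smiles: list[str], radius: int = FP_RADIUS, n_bits: int = FP_NBITS
) -> np.ndarray:
    """Circular fingerprints as a (n, n_bits) boolean array."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles), n_bits), dtype=bool)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ChemParseError(f"cannot parse SMILES {smi!r}")
        out[i, list(gen.GetFingerprint(mol).GetOnBits())] = True
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two fingerprint bit vectors.

    Defined as 1.0 when both fingerprints are empty.  The two fingerprints
    must have been generated with identical parameters (same length).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


@dataclass
class Dendrogram:
    """Average-linkage merge tree over 1 - Tanimoto distances."""

    linkage_matrix: np.ndarray  # scipy hierarchical-clustering encoding
    labels: list[str]
    metadata: dict = field(default_factory=dict)

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def esc(label: str) -> str:
            return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "_").replace(":", "_").replace(";", "_")

        def render(node: int) -> str:
            if node < n:
                return esc(self.labels[node])
            left, right, height, _ = self.linkage_matrix[node - n]
            parts = []
            for child in (int(left), int(right)):
                child_height = heights[child]
                parts.append(f"{render(child)}:{height - child_height:.6g}")
            heights[node] = height
            return "(" + ",".join(parts) + ")"

        # fill heights bottom-up before rendering branch lengths of inner nodes
        for k, (_, _, height, _) in enumerate(self.linkage_matrix):
            heights[n + k] = height
        return render(n + len(self.linkage_matrix) - 1) + ";"


def cluster_products(
    smiles: list[str],
    labels: list[str] | None = None,
    radius: int = FP_RADIUS,
    n_bits: int = FP_NBITS,
) -> Dendrogram:
    """Agglomerate products by average linkage on 1 - Tanimoto distance.

    Requires at least two structures.  Leaf order follows the input order, so
    identical inputs give identical trees.
    """
    if len(smiles) < 2:
        raise ValueError("clustering needs at least two products")
    labels = list(labels) if labels is not None else list(smiles)
    if len(labels) != len(smiles):
        raise ValueError("labels and smiles length mismatch")
    fps = morgan_fingerprints(smiles, radius=radius, n_bits=n_bits)
    n = len(smiles)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    link = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(
        linkage_matrix=link,
        labels=labels,
        metadata={"fingerprint": "morgan", "radius": radius, "n_bits": n_bits,
                  "metric": "1-tanimoto", "linkage": "average"},
    )
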