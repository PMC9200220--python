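"""Structural clustering of screening hits.

Circular (Morgan radius-2, 2048-bit) fingerprints, Tanimoto distances,
average-linkage agglomerative clustering cut to k groups, and medoid
representatives.  Inputs are sorted by compound id before any distance
computation so the partition is invariant under input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError

DEFAULT_N_BITS = 2048
DEFAULT_FP_RADIUS = 2


@dataclass
class FingerprintSet:
    ids: list[str]
    bits: np.ndarray  # (n, n_bits) bool
    failed_ids: list[str]

    def __len__(self) -> int:
        return len(self.ids)


def fingerprints(
    smiles_records: Iterable[tuple[str, str]],
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_FP_RADIUS,
) -> FingerprintSet:
    """Morgan bit fingerprints for (smiles, id) records; failures reported
    in failed_ids and excluded."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    failed: list[str] = []
    seen: set[str] = set()
    for smiles, cid in smiles_records:
        if cid in seen:
            raise ConfigError(f"duplicate compound id {cid!r}")
        seen.add(cid)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failed.append(cid)
            continue
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=bool)
        arr[list(fp.GetOnBits())] = True
        ids.append(cid)
        rows.append(arr)
    bits = np.array(rows) if rows else np.zeros((0, n_bits), dtype=bool)
    return FingerprintSet(ids=ids, bits=bits, failed_ids=failed)


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b|; two empty bit sets are at distance 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return 1.0 - int(np.sum(a & b)) / union


def distance_matrix(fps: FingerprintSet) -> np.ndarray:
    """Full symmetric Tanimoto distance matrix (vectorized)."""
    b = fps.bits.astype(np.float64)
    inter = b @ b.T
    counts = b.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Clustering:
    labels: dict[str, int]  # id -> cluster index in 1..k
    k: int
    linkage: str = "average"

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid in sorted(self.labels):
            out.setdefault(self.labels[cid], []).append(cid)
        return out


def cluster(fps: FingerprintSet, k: int = 6, linkage_method: str = "average") -> Clustering:
    """Average-linkage agglomerative clustering on Tanimoto distances,
    dendrogram cut to k clusters."""
    if len(fps) < k:
        raise ConfigError(f"need at least k={k} compounds, have {len(fps)}")
    order = np.argsort(np.array(fps.ids))
    ids = [fps.ids[i] for i in order]
    bits = fps.bits[order]
    sub = FingerprintSet(ids=ids, bits=bits, failed_ids=[])
    d = distance_matrix(sub)
    z = linkage(squareform(d, checks=False), method=linkage_method)
    flat = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance for stable output
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for cid, raw in zip(ids, flat):
        if raw not in remap:
            remap[raw] = len(remap) + 1
        labels[cid] = remap[raw]
    return Clustering(labels=labels, k=len(remap), linkage=linkage_method)


def representatives(fps: FingerprintSet, clustering: Clustering) -> dict[int, str]:
    """Cluster medoids: member minimizing summed intra-cluster Tanimoto
    distance, ties broken by id order."""
    idx = {cid: i for i, cid in enumerate(fps.ids)}
    d = distance_matrix(fps)
    out: dict[int, str] = {}
    for c, members in clustering.members().items():
        rows = [idx[m] for m in members]
        sub = d[np.ix_(rows, rows)]
        sums = sub.sum(axis=1)
        best = int(np.lexsort((np.array(members, dtype=object), sums))[0])
        out[c] = members[best]
    return out


def write_clusters(path, clustering: Clustering, reps: dict[int, str]) -> None:
    rep_ids = set(reps.values())
    with open(path, "w") as fh:
        fh.write("id\tcluster\tis_representative\n")
        for cid in sorted(clustering.labels):
            fh.write(f"{cid}\t{clustering.labels[cid]}\t{int(cid in rep_ids)}\n")
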