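"""Substructure-sentence featurization and embedding tables.

A molecule is rendered as an ordered "sentence" of Morgan-environment
substructure identifiers (one per heavy atom per radius), which are then
embedded with a small skip-gram model and aggregated into a fixed-length
real vector.  The same machinery featurizes pocket pseudo-molecules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigError, EmptySentenceError, MoleculeParseError

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADII = (0, 1)
DEFAULT_DIM = 300
UNK_TOKEN = "UNK"


@dataclass(frozen=True)
class SubstructureSentence:
    """Ordered substructure identifiers for one molecule.

    Tokens are emitted per heavy atom (in atom-index order) and per radius
    (ascending), so ``len(tokens) == n_heavy_atoms * n_radii``.  When an
    atom has no resolved environment at some radius (e.g. an isolated atom
    at radius 1) the last resolved identifier for that atom is repeated,
    keeping the token count invariant.
    """

    tokens: tuple[str, ...]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class EmbeddingTable:
    """Token -> vector lookup with a total fallback for unseen tokens."""

    dim: int
    vectors: dict[str, np.ndarray]
    unk_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dim)
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ConfigError(
                    f"vector for token {tok!r} has length {vec.shape}, expected {self.dim}"
                )
        if self.unk_vector.shape != (self.dim,):
            raise ConfigError("unk_vector length does not match dim")

    def lookup(self, token: str) -> np.ndarray:
        """Total lookup: unknown tokens return the UNK vector, never raise."""
        return self.vectors.get(token, self.unk_vector)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def save(self, path) -> None:
        """Write as TSV: header ``token<TAB>d0..d{dim-1}``, one row per token.

        Floats are written with 17 significant digits so load() round-trips
        bit-identically.
        """
        with open(path, "w") as fh:
            header = "token\t" + "\t".join(f"d{i}" for i in range(self.dim))
            fh.write(header + "\n")
            fh.write(self._row(UNK_TOKEN, self.unk_vector))
            for tok in sorted(self.vectors):
                fh.write(self._row(tok, self.vectors[tok]))

    @staticmethod
    def _row(token: str, vec: np.ndarray) -> str:
        return token + "\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n"

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "token":
                raise ConfigError(f"not an embedding table: {path}")
            dim = len(header) - 1
            vectors: dict[str, np.ndarray] = {}
            unk = None
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                tok = parts[0]
                vec = np.array([float(x) for x in parts[1:]])
                if tok == UNK_TOKEN:
                    unk = vec
                else:
                    vectors[tok] = vec
        return cls(dim=dim, vectors=vectors, unk_vector=unk)


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length real feature vector for a molecule or pocket."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ConfigError(f"non-finite feature vector for {self.source_id!r}")


def mol_to_sentence(
    mol: Chem.Mol, radii: Sequence[int] = DEFAULT_RADII, source_id: str = ""
) -> SubstructureSentence:
    """Render a molecule as an ordered sentence of Morgan identifiers.

    For each heavy atom in index order, one identifier is emitted per radius
    in ascending order.  Hydrogens are stripped first.
    """
    if mol is None:
        raise MoleculeParseError("molecule is None", record_id=source_id)
    radii = tuple(sorted(set(int(r) for r in radii)))
    if not radii or radii[0] < 0:
        raise ConfigError(f"invalid radii {radii}")
    mol = Chem.RemoveHs(mol, sanitize=False)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise MoleculeParseError("molecule has no heavy atoms", record_id=source_id)

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radii))
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    per_atom: dict[int, dict[int, int]] = {i: {} for i in range(n_atoms)}
    for identifier, hits in out.GetBitInfoMap().items():
        for atom_idx, rad in hits:
            per_atom[atom_idx][rad] = identifier

    tokens: list[str] = []
    for atom_idx in range(n_atoms):
        resolved = per_atom[atom_idx]
        last = None
        for rad in radii:
            if rad in resolved:
                last = resolved[rad]
            elif last is None:
                # radius 0 always resolves for a real atom; guard anyway
                last = resolved.get(0, 0)
            tokens.append(str(last))
    return SubstructureSentence(tokens=tuple(tokens), source_id=source_id)


def smiles_to_sentence(
    smiles: str, radii: Sequence[int] = DEFAULT_RADII, source_id: str = ""
) -> SubstructureSentence:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES {smiles!r}", record_id=source_id)
    return mol_to_sentence(mol, radii=radii, source_id=source_id)


def embed_molecule(
    sentence: SubstructureSentence,
    table: EmbeddingTable,
    aggregation: str = "sum",
) -> FeatureVector:
    """Aggregate the token vectors of a sentence into one feature vector.

    Default aggregation is the unweighted sum; ``aggregation="mean"`` divides
    by the token count.  Unknown tokens contribute the UNK vector.
    """
    if len(sentence) == 0:
        raise EmptySentenceError(f"empty sentence for {sentence.source_id!r}")
    if aggregation not in ("sum", "mean"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    acc = np.zeros(table.dim)
    for tok in sentence.tokens:
        acc += table.lookup(tok)
    if aggregation == "mean":
        acc /= len(sentence)
    return FeatureVector(values=acc, source_id=sentence.source_id)


# ---------------------------------------------------------------------------
# skip-gram embedding trainer
# ---------------------------------------------------------------------------


def train_embedding(
    corpus: Sequence[SubstructureSentence],
    dim: int = DEFAULT_DIM,
    window: int = 10,
    min_count: int = 1,
    seed: int = 0,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
) -> EmbeddingTable:
    """Train a skip-gram-with-negative-sampling table on a sentence corpus.

    Tokens occurring fewer than ``min_count`` times are pooled into a
    dedicated UNK token whose vector is trained alongside the vocabulary;
    with no rare tokens the UNK vector is zero.  Single-threaded and fully
    deterministic for a fixed seed.
    """
    if len(corpus) == 0:
        raise ConfigError("empty training corpus")
    if dim < 1:
        raise ConfigError("dim must be >= 1")

    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1

    kept = {t for t, c in counts.items() if c >= min_count}
    has_unk = len(kept) < len(counts)
    # deterministic vocab order: by descending count, then token
    vocab = sorted(kept, key=lambda t: (-counts[t], t))
    if has_unk:
        vocab.append(UNK_TOKEN)
        counts[UNK_TOKEN] = sum(c for t, c in counts.items() if t not in kept)
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    def tok2idx(tok: str) -> int:
        return index.get(tok, index.get(UNK_TOKEN, -1))

    sents_idx = []
    for sent in corpus:
        idxs = [tok2idx(t) for t in sent.tokens]
        sents_idx.append(np.array([i for i in idxs if i >= 0], dtype=np.int64))

    # (center, context) pairs within the window
    centers, contexts = [], []
    for idxs in sents_idx:
        n = len(idxs)
        for pos in range(n):
            lo, hi = max(0, pos - window), min(n, pos + window + 1)
            for ctx in range(lo, hi):
                if ctx != pos:
                    centers.append(idxs[pos])
                    contexts.append(idxs[ctx])
    if not centers:
        raise ConfigError("corpus yields no training pairs (all sentences length 1?)")
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    n_pairs = len(centers)
    batch = 1024
    total_steps = epochs * n_pairs
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start : start + batch]
            c = centers[sel]
            pos = contexts[sel]
            neg = rng.choice(V, size=(len(sel), negatives), p=neg_p)
            cur_lr = max(lr * (1 - step / total_steps), lr * 1e-2)
            step += len(sel)

            v_c = W_in[c]  # (B, d)
            # positive examples
            logit_p = np.clip(np.einsum("bd,bd->b", v_c, W_out[pos]), -30, 30)
            score_p = 1.0 / (1.0 + np.exp(-logit_p))
            g_p = (score_p - 1.0)[:, None]  # (B, 1)
            # negative examples
            v_n = W_out[neg]  # (B, K, d)
            logit_n = np.clip(np.einsum("bd,bkd->bk", v_c, v_n), -30, 30)
            score_n = 1.0 / (1.0 + np.exp(-logit_n))
            g_n = score_n[:, :, None]  # (B, K, 1)

            grad_c = g_p * W_out[pos] + np.einsum("bkd,bk->bd", v_n, score_n)
            np.add.at(W_out, pos, -cur_lr * g_p * v_c)
            np.add.at(
                W_out,
                neg.ravel(),
                (-cur_lr * g_n * v_c[:, None, :]).reshape(-1, dim),
            )
            np.add.at(W_in, c, -cur_lr * grad_c)

    vectors = {t: W_in[i].copy() for t, i in index.items() if t != UNK_TOKEN}
    unk = W_in[index[UNK_TOKEN]].copy() if has_unk else np.zeros(dim)
    return EmbeddingTable(dim=dim, vectors=vectors, unk_vector=unk)


# ---------------------------------------------------------------------------
# library readers
# ---------------------------------------------------------------------------


def read_smi(source) -> Iterator[tuple[str, str]]:
    """Yield (smiles, identifier) records from .smi text.

    Accepts a path or an open text handle.  Records are whitespace-separated
    ``SMILES id``; blank lines and ``#`` comments are ignored; a missing id
    defaults to the 1-based record number.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh, close = source, False
    try:
        n = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n += 1
            parts = line.split()
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else str(n)
            yield smiles, ident
    finally:
        if close:
            fh.close()


def read_sdf(path) -> Iterator[tuple[Chem.Mol, str]]:
    """Yield (mol, identifier) from an SDF file; unparseable records are skipped."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        ident = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(i + 1)
        yield mol, ident


def featurize_library(
    records: Iterable[tuple[str, str]],
    table: EmbeddingTable,
    radii: Sequence[int] = DEFAULT_RADII,
    aggregation: str = "sum",
) -> tuple[list[FeatureVector], list[str]]:
    """Featurize SMILES records; returns (vectors, failed_ids)."""
    vecs: list[FeatureVector] = []
    failed: list[str] = []
    for smiles, ident in records:
        try:
            sent = smiles_to_sentence(smiles, radii=radii, source_id=ident)
            vecs.append(embed_molecule(sent, table, aggregation=aggregation))
        except (MoleculeParseError, EmptySentenceError):
            failed.append(ident)
    return vecs, failed


def write_vectors(path, vectors: Sequence[FeatureVector]) -> None:
    with open(path, "w") as fh:
        for fv in vectors:
            fh.write(fv.source_id + "\t" + "\t".join(f"{v:.17g}" for v in fv.values) + "\n")


def read_vectors(path) -> list[FeatureVector]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(
                FeatureVector(values=np.array([float(x) for x in parts[1:]]), source_id=parts[0])
            )
    return out
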