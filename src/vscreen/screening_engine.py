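"""Streaming library screening against a fixed pocket vector.

Compounds are featurized, concatenated after the pocket vector, scored in
batches, and ranked; selection by score cutoff or top fraction, recall at
top fractions, and rule-of-five filtering live here too.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chem_features import (
    DEFAULT_RADII,
    EmbeddingTable,
    FeatureVector,
    embed_molecule,
    smiles_to_sentence,
)
from .dfcnn_core import DFCNNParams, score
from .errors import ConfigError, EmptySentenceError, MoleculeParseError, UndefinedMetricError


@dataclass
class ScreeningResult:
    """Ranked (compound_id, score) table; descending score, ties by id."""

    rows: list[tuple[str, float]]
    pocket_id: str = ""
    model_id: str = ""
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for cid, s in self.rows:
                fh.write(f"{cid}\t{s:.17g}\n")

    @classmethod
    def load(cls, path, pocket_id: str = "", model_id: str = "") -> "ScreeningResult":
        rows = []
        with open(path) as fh:
            for line in fh:
                cid, s = line.rstrip("\n").split("\t")
                rows.append((cid, float(s)))
        return cls(rows=_ranked(rows), pocket_id=pocket_id, model_id=model_id)


@dataclass
class SelectionReport:
    mode: str  # "cutoff" | "top_fraction"
    parameter: float
    selected_ids: list[str]

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def _ranked(rows: list[tuple[str, float]]) -> list[tuple[str, float]]:
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def _pocket_values(pocket_vec) -> np.ndarray:
    return pocket_vec.values if isinstance(pocket_vec, FeatureVector) else np.asarray(pocket_vec)


def screen_vectors(
    model: DFCNNParams,
    pocket_vec,
    ligand_vectors: Iterable[tuple[str, np.ndarray]],
    batch_size: int = 1024,
    pocket_id: str = "",
    model_id: str = "",
) -> ScreeningResult:
    """Score pre-featurized ligand vectors against one pocket vector.

    Input rows are pocket ++ ligand (pocket first).  The result is
    independent of batch_size.
    """
    pv = _pocket_values(pocket_vec)
    if 2 * len(pv) != model.config.input_dim:
        raise ConfigError(
            f"model input_dim {model.config.input_dim} != 2 x pocket dim {len(pv)}"
        )
    rows: list[tuple[str, float]] = []
    ids_buf: list[str] = []
    vec_buf: list[np.ndarray] = []

    def flush():
        if not ids_buf:
            return
        batch = np.column_stack(
            [np.tile(pv, (len(vec_buf), 1)), np.array(vec_buf)]
        )
        for cid, s in zip(ids_buf, score(model, batch)):
            rows.append((cid, float(s)))
        ids_buf.clear()
        vec_buf.clear()

    for cid, vec in ligand_vectors:
        ids_buf.append(cid)
        vec_buf.append(np.asarray(vec))
        if len(ids_buf) >= batch_size:
            flush()
    flush()
    return ScreeningResult(
        rows=_ranked(rows), pocket_id=pocket_id, model_id=model_id, n_failed=0
    )


def screen_library(
    model: DFCNNParams,
    table: EmbeddingTable,
    pocket_vec,
    library: Iterable[tuple[str, str]],
    batch_size: int = 1024,
    radii: Sequence[int] = DEFAULT_RADII,
    aggregation: str = "sum",
    pocket_id: str = "",
    model_id: str = "",
) -> ScreeningResult:
    """Stream (smiles, id) records: featurize, score, rank.

    Unparseable or unfeaturizable records are counted in n_failed and not
    scored.  An empty library yields an empty result.
    """
    n_failed = 0

    def vectors():
        nonlocal n_failed
        for smiles, cid in library:
            try:
                sent = smiles_to_sentence(smiles, radii=radii, source_id=cid)
                fv = embed_molecule(sent, table, aggregation=aggregation)
            except (MoleculeParseError, EmptySentenceError):
                n_failed += 1
                continue
            yield cid, fv.values

    result = screen_vectors(
        model, pocket_vec, vectors(), batch_size=batch_size,
        pocket_id=pocket_id, model_id=model_id,
    )
    result.n_failed = n_failed
    return result


def select(result: ScreeningResult, mode: str, parameter: float) -> SelectionReport:
    """Select by score cutoff or by top fraction of the ranked rows."""
    if mode == "cutoff":
        if not 0.0 < parameter <= 1.0:
            raise ConfigError("cutoff must be in (0, 1]")
        ids = [cid for cid, s in result.rows if s >= parameter]
    elif mode == "top_fraction":
        if not 0.0 < parameter <= 1.0:
            raise ConfigError("top fraction must be in (0, 1]")
        n_sel = math.ceil(parameter * len(result.rows))
        ids = [cid for cid, _ in result.rows[:n_sel]]
    else:
        raise ConfigError(f"unknown selection mode {mode!r}")
    return SelectionReport(mode=mode, parameter=parameter, selected_ids=ids)


def recall_at_top(
    result: ScreeningResult,
    active_ids: set[str],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> dict[float, float]:
    """recall(f) = fraction of actives ranked within the top ceil(f*n) rows."""
    if not active_ids:
        raise UndefinedMetricError("recall undefined with zero active compounds")
    scored = set(result.ids())
    missing = set(active_ids) - scored
    if missing:
        raise ConfigError(f"active ids not in the screening result: {sorted(missing)[:5]}")
    n = len(result.rows)
    out = {}
    for f in fractions:
        top = set(result.ids()[: math.ceil(f * n)])
        out[f] = len(top & active_ids) / len(active_ids)
    return out


def lipinski_pass(mw: float, logp: float, hbd: int, hba: int) -> bool:
    """Rule-of-five filter with inclusive bounds."""
    for v in (mw, logp, hbd, hba):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ConfigError("missing descriptor for Lipinski filter")
    return mw <= 500 and logp <= 5 and hbd <= 5 and hba <= 10


def lipinski_descriptors(smiles: str) -> tuple[float, float, int, int]:
    """(MW, logP, H-bond donors, H-bond acceptors) from a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES {smiles!r}")
    return (
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
    )


def write_manifest(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
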