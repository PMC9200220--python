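"""Synthetic fixtures with known ground truth for every pipeline stage.

Provides a planted-signal pocket/ligand "binding world" (stands in for a
complex-derived training set), cross-combination pair sampling, toy PDB
complexes with exact planted pocket distances, a fragment-grammar SMILES
generator, and labeled active/decoy evaluation libraries.  Every generator
is pure given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .dfcnn_core import PairSample
from .errors import ConfigError

OBSERVED_DIM = 300


@dataclass
class BindingWorld:
    """Planted-signal world: binding iff latent dot-product >= threshold."""

    pocket_latents: dict[str, np.ndarray]
    pocket_observed: dict[str, np.ndarray]
    ligand_latents: dict[str, np.ndarray]
    ligand_observed: dict[str, np.ndarray]
    threshold: float
    noise_sd: float
    k: int
    seed: int
    # maps used to project fresh latents into observed space
    pocket_map: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ligand_map: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    latent_loc: float = 0.0
    latent_scale: float = 1.0

    def compatibility(self, pocket_id: str, ligand_id: str) -> float:
        return float(self.pocket_latents[pocket_id] @ self.ligand_latents[ligand_id])

    def binds(self, pocket_id: str, ligand_id: str) -> bool:
        return self.compatibility(pocket_id, ligand_id) >= self.threshold

    def binding_pairs(self) -> set[tuple[str, str]]:
        return {
            (p, l)
            for p in self.pocket_latents
            for l in self.ligand_latents
            if self.binds(p, l)
        }

    def prevalence(self) -> float:
        n = len(self.pocket_latents) * len(self.ligand_latents)
        return len(self.binding_pairs()) / n


def generate_world(
    n_pockets: int = 30,
    n_ligands: int = 200,
    k: int = 4,
    noise_sd: float = 0.05,
    threshold: float | None = None,
    target_prevalence: float = 0.2,
    seed: int = 0,
    latent_loc: float = 2.5,
    latent_scale: float = 0.15,
) -> BindingWorld:
    """Generate a planted world; threshold auto-tuned to target_prevalence.

    Latents live in a shifted Gaussian (mean latent_loc/sqrt(k) per axis) so
    that the pairwise dot product has a strong near-linear component — the
    label signal is recoverable from the observed vectors.  Observed vectors
    are a fixed random linear map of the latents plus isotropic noise.
    """
    if k > OBSERVED_DIM:
        raise ConfigError(f"latent dim k={k} exceeds observed dim {OBSERVED_DIM}")
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigError("target_prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mu = latent_loc / np.sqrt(k)
    P_lat = mu + latent_scale * rng.standard_normal((n_pockets, k))
    L_lat = mu + latent_scale * rng.standard_normal((n_ligands, k))
    # fixed orthonormal-ish projection maps, one per side
    pocket_map = rng.standard_normal((k, OBSERVED_DIM)) / np.sqrt(k)
    ligand_map = rng.standard_normal((k, OBSERVED_DIM)) / np.sqrt(k)
    P_obs = P_lat @ pocket_map + noise_sd * rng.standard_normal((n_pockets, OBSERVED_DIM))
    L_obs = L_lat @ ligand_map + noise_sd * rng.standard_normal((n_ligands, OBSERVED_DIM))

    if threshold is None:
        compat = P_lat @ L_lat.T
        threshold = float(np.quantile(compat, 1.0 - target_prevalence))

    pids = [f"P{i:04d}" for i in range(n_pockets)]
    lids = [f"L{i:05d}" for i in range(n_ligands)]
    return BindingWorld(
        pocket_latents={p: P_lat[i] for i, p in enumerate(pids)},
        pocket_observed={p: P_obs[i] for i, p in enumerate(pids)},
        ligand_latents={l: L_lat[i] for i, l in enumerate(lids)},
        ligand_observed={l: L_obs[i] for i, l in enumerate(lids)},
        threshold=threshold,
        noise_sd=noise_sd,
        k=k,
        seed=seed,
        pocket_map=pocket_map,
        ligand_map=ligand_map,
        latent_loc=latent_loc,
        latent_scale=latent_scale,
    )


def make_pair_dataset(
    world: BindingWorld,
    negative_strategy: str = "cross_combination",
    ratio: float = 1.0,
    seed: int = 0,
    max_positives: int | None = None,
) -> list[PairSample]:
    """Positive pairs are true binders; negatives pair pockets with ligands
    that bind some *other* pocket, excluding all true-binding pairs."""
    if negative_strategy != "cross_combination":
        raise ConfigError(f"unknown negative strategy {negative_strategy!r}")
    rng = np.random.default_rng(seed)
    binding = sorted(world.binding_pairs())
    if not binding:
        raise ConfigError("world has no binding pairs; cannot build positives")
    if max_positives is not None and len(binding) > max_positives:
        sel = rng.choice(len(binding), size=max_positives, replace=False)
        binding = [binding[i] for i in sorted(sel)]
    binding_set = world.binding_pairs()

    # ligands that bind at least one pocket (cross-combination pool)
    binder_ligands = sorted({l for _, l in binding_set})
    pockets = sorted(world.pocket_latents)
    candidates = [
        (p, l)
        for p in pockets
        for l in binder_ligands
        if (p, l) not in binding_set
    ]
    n_neg = int(round(ratio * len(binding)))
    if len(candidates) < n_neg:
        raise ConfigError(
            f"only {len(candidates)} cross-combination negatives available, need {n_neg}"
        )
    sel = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = [candidates[i] for i in sorted(sel)]

    samples = [
        PairSample(
            pocket=world.pocket_observed[p],
            ligand=world.ligand_observed[l],
            label=1,
            provenance="positive",
        )
        for p, l in binding
    ] + [
        PairSample(
            pocket=world.pocket_observed[p],
            ligand=world.ligand_observed[l],
            label=0,
            provenance="cross_combination",
        )
        for p, l in negatives
    ]
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


# ---------------------------------------------------------------------------
# toy PDB complexes
# ---------------------------------------------------------------------------

# idealized heavy-atom templates (element, name, x, y, z)
_GLY_TEMPLATE = [
    ("N", "N", -1.458, 0.0, 0.0),
    ("C", "CA", 0.0, 0.0, 0.0),
    ("C", "C", 0.551, 1.417, 0.0),
    ("O", "O", 1.766, 1.577, 0.0),
]
_ALA_TEMPLATE = _GLY_TEMPLATE + [("C", "CB", 0.607, -0.888, 1.075)]
# 3-atom rigid ligand centered near the origin
_LIGAND_TEMPLATE = [
    ("C", "C1", -0.75, 0.0, 0.0),
    ("C", "C2", 0.75, 0.0, 0.0),
    ("O", "O1", 1.45, 1.1, 0.0),
]


def _min_dist_at(template_xyz: np.ndarray, u: np.ndarray, t: float, lig_xyz: np.ndarray) -> float:
    placed = template_xyz + t * u
    d = np.linalg.norm(placed[:, None, :] - lig_xyz[None, :, :], axis=2)
    return float(d.min())


def _place_at_distance(template_xyz, u, target, lig_xyz) -> np.ndarray:
    """Translate the template along u so its min distance to the ligand is
    exactly `target` (bisection; min distance is monotone for t past the
    ligand radius)."""
    lo = float(np.linalg.norm(lig_xyz, axis=1).max() + np.linalg.norm(template_xyz, axis=1).max())
    hi = lo + target + 10.0
    while _min_dist_at(template_xyz, u, hi, lig_xyz) < target:
        hi += 10.0
    if _min_dist_at(template_xyz, u, lo, lig_xyz) > target:
        lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _min_dist_at(template_xyz, u, mid, lig_xyz) < target:
            lo = mid
        else:
            hi = mid
    return template_xyz + 0.5 * (lo + hi) * u


def generate_toy_complex(
    n_residues: int = 8,
    n_near: int = 4,
    radius: float = 10.0,
    seed: int = 0,
    distances: list[float] | None = None,
) -> tuple[str, dict]:
    """Emit PDB text for a toy complex plus ground-truth pocket metadata.

    Exactly n_near residues have min distance <= radius to the planted
    ligand.  `distances` overrides the per-residue min distances (its first
    n_near entries must be <= radius, the rest > radius).  Metadata records
    the planted min distance of every residue.
    """
    if n_near > n_residues:
        raise ConfigError("n_near cannot exceed n_residues")
    rng = np.random.default_rng(seed)
    if distances is None:
        near = rng.uniform(0.35 * radius, 0.92 * radius, size=n_near)
        far = rng.uniform(1.08 * radius, 2.5 * radius, size=n_residues - n_near)
        distances = list(np.concatenate([near, far]))
    else:
        if len(distances) != n_residues:
            raise ConfigError("len(distances) must equal n_residues")
        n_ok = sum(1 for d in distances[:n_near] if d <= radius)
        if n_ok != n_near or any(d <= radius for d in distances[n_near:]):
            raise ConfigError("distances inconsistent with n_near/radius")

    lig_xyz = np.array([[x, y, z] for _, _, x, y, z in _LIGAND_TEMPLATE])
    lines: list[str] = []
    serial = 1
    meta_res: dict[int, dict] = {}
    for i, d in enumerate(distances):
        template = _ALA_TEMPLATE if i % 2 else _GLY_TEMPLATE
        res_name = "ALA" if i % 2 else "GLY"
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        txyz = np.array([[x, y, z] for _, _, x, y, z in template])
        placed = _place_at_distance(txyz, u, float(d), lig_xyz)
        res_num = i + 1
        for (el, name, *_), xyz in zip(template, placed):
            lines.append(_pdb_line("ATOM", serial, name, res_name, "A", res_num, xyz, el))
            serial += 1
        dmin = float(
            np.linalg.norm(placed[:, None, :] - lig_xyz[None, :, :], axis=2).min()
        )
        meta_res[res_num] = {"res_name": res_name, "min_dist": dmin, "near": dmin <= radius}
    for (el, name, x, y, z) in _LIGAND_TEMPLATE:
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "A", 900, np.array([x, y, z]), el))
        serial += 1
    lines.append("END")
    meta = {
        "radius": radius,
        "ligand_id": ("LIG", "A", 900),
        "residues": meta_res,
        "near_residues": sorted(r for r, m in meta_res.items() if m["near"]),
        "n_protein_atoms": serial - 1 - len(_LIGAND_TEMPLATE),
    }
    return "\n".join(lines) + "\n", meta


def _pdb_line(rec, serial, name, res_name, chain, res_num, xyz, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{rec:<6s}{serial:>5d} {name_field}{'':1s}{res_name:>3s} {chain}"
        f"{res_num:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


# ---------------------------------------------------------------------------
# SMILES library generation
# ---------------------------------------------------------------------------

_CORES = [
    "c1ccc({a})cc1",
    "c1ccc({a})nc1",
    "c1cc({a})ccc1{b}",
    "C1CCN({a})CC1",
    "C1CCC({a})CC1",
    "c1ccc2c(c1)cc({a})cc2",
    "c1ccc({a})c({b})c1",
    "O=C({a})N{b}",
    "O=S(=O)({a})N{b}",
]
_SUBS = [
    "C", "CC", "CCC", "CCO", "CO", "CN", "CCN", "O", "N", "F", "Cl", "Br",
    "C(C)C", "C(=O)O", "C(=O)N", "C(=O)OC", "CC(=O)N", "OC", "OCC", "N(C)C",
    "CCN(C)C", "C#N", "C(F)(F)F", "c2ccccc2", "c2ccncc2", "C2CCCCC2",
    "CNC(=O)C", "COC", "CS", "CSC", "CC(O)C", "[H]",
]
# fragments that cannot be extended by string concatenation
_TERMINAL_SUBS = {"F", "Cl", "Br", "C#N", "C(F)(F)F", "[H]"}
# recipes guaranteed to violate one Lipinski rule each
_VIOLATORS = [
    "C" * 28,                                     # logP > 5
    "c1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccccc5)cc4)cc3)cc2)cc1CCCCCCCCCCCC",  # MW > 500
    "OCC(O)C(O)C(O)C(O)C(O)C(O)CO",               # H-bond donors > 5
    "COCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOC",          # H-bond acceptors > 10
]


def generate_smiles_library(n: int, seed: int = 0) -> str:
    """Generate .smi text with n unique, RDKit-parseable SMILES.

    Molecules are assembled from a small fragment grammar (aromatic and
    aliphatic cores with drug-like substituents).  A few deterministic
    recipes violating each rule-of-five bound are interleaved so that the
    library spans the Lipinski pass/fail boundary.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[tuple[str, str]] = []
    attempts = 0
    vi = 0
    while len(records) < n and attempts < 100 * n + 1000:
        attempts += 1
        if len(records) % 40 == 10 and vi < len(_VIOLATORS):
            smi = _VIOLATORS[vi % len(_VIOLATORS)]
            vi += 1
        else:
            core = _CORES[rng.integers(len(_CORES))]

            def chain() -> str:
                # 1-3 fragments concatenated; a terminal fragment ends the chain
                parts = []
                for _ in range(int(rng.integers(1, 4))):
                    frag = _SUBS[rng.integers(len(_SUBS))]
                    parts.append(frag)
                    if frag in _TERMINAL_SUBS:
                        break
                return "".join(parts)

            try:
                smi = core.format(a=chain(), b=chain())
            except (IndexError, KeyError):
                continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        records.append((canon, f"CMPD{len(records):06d}"))
    if len(records) < n:
        raise ConfigError(f"could only generate {len(records)} unique molecules")
    return "".join(f"{s}\t{i}\n" for s, i in records)


# ---------------------------------------------------------------------------
# labeled evaluation libraries
# ---------------------------------------------------------------------------


@dataclass
class LabeledLibrary:
    """DUD.E-style labeled library tied to one pocket of a BindingWorld."""

    compounds: list[tuple[str, str]]  # (smiles, id)
    active_ids: set[str]
    decoy_ids: set[str]
    vectors: dict[str, np.ndarray]
    pocket_id: str
    pocket_vector: np.ndarray

    def to_smi(self) -> str:
        return "".join(f"{s}\t{i}\n" for s, i in self.compounds)


def generate_labeled_library(
    world: BindingWorld,
    n_decoys: int = 500,
    seed: int = 0,
    pocket_id: str | None = None,
) -> LabeledLibrary:
    """Actives are the chosen pocket's true binders; decoys are non-binding
    ligands, topped up with fresh world-distribution ligands if needed."""
    rng = np.random.default_rng(seed)
    binding = world.binding_pairs()
    if pocket_id is None:
        counts = {p: 0 for p in world.pocket_latents}
        for p, _ in binding:
            counts[p] += 1
        pocket_id = max(sorted(counts), key=lambda p: counts[p])
    actives = sorted(l for p, l in binding if p == pocket_id)
    if not actives:
        raise ConfigError(f"pocket {pocket_id} has no binding ligands")
    p_lat = world.pocket_latents[pocket_id]

    decoys = sorted(
        l for l in world.ligand_latents
        if l not in set(actives) and not world.binds(pocket_id, l)
    )
    if len(decoys) > n_decoys:
        sel = rng.choice(len(decoys), size=n_decoys, replace=False)
        decoys = [decoys[i] for i in sorted(sel)]
    vectors = {l: world.ligand_observed[l] for l in actives + decoys}

    # synthesize additional decoys from the same latent distribution
    extra_needed = n_decoys - len(decoys)
    mu = world.latent_loc / np.sqrt(world.k)
    i = 0
    while extra_needed > 0:
        lat = mu + world.latent_scale * rng.standard_normal(world.k)
        if float(p_lat @ lat) >= world.threshold:
            continue
        obs = lat @ world.ligand_map + world.noise_sd * rng.standard_normal(OBSERVED_DIM)
        lid = f"D{i:06d}"
        i += 1
        decoys.append(lid)
        vectors[lid] = obs
        extra_needed -= 1

    ids = actives + decoys
    smi_lines = generate_smiles_library(len(ids), seed=seed).splitlines()
    compounds = [(line.split("\t")[0], ids[j]) for j, line in enumerate(smi_lines)]
    return LabeledLibrary(
        compounds=compounds,
        active_ids=set(actives),
        decoy_ids=set(decoys),
        vectors=vectors,
        pocket_id=pocket_id,
        pocket_vector=world.pocket_observed[pocket_id],
    )
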