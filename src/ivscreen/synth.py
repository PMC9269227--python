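"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here tries to simulate docking energetics; the generators emulate
the *statistical structure* the screen assumes — true targets bind the
query better than both the background panel and the decoys — plus the
file plumbing (PDB/SDF/SMILES/TSV) so the whole pipeline runs with no
download and no docking engine.

Defaults: non-binder query affinities ~ Normal(-6.0, 0.8) kcal/mol, decoy
affinities ~ Normal(-6.5, 0.8), and a planted shift of -3.0 kcal/mol on
true (compound, target) pairs.  These straddle the -7.5 kcal/mol
retention threshold, so both filter branches are exercised: background
targets occasionally pass by chance while planted targets essentially
always do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Recipe for a recorded affinity matrix with planted true targets."""

    n_targets: int = 50
    n_planted: int = 2
    base_affinity_mean: float = -6.0   # kcal/mol, non-binders
    base_affinity_sd: float = 0.8
    planted_shift: float = -3.0        # kcal/mol added on true pairs (< 0)
    decoy_affinity_mean: float = -6.5  # kcal/mol
    decoy_affinity_sd: float = 0.8
    n_compounds: int = 3
    n_decoys: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_targets:
            raise ParameterError("n_planted cannot exceed n_targets")
        if self.base_affinity_sd < 0 or self.decoy_affinity_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.planted_shift > 0:
            raise ParameterError("planted_shift must be <= 0 (stronger binding)")
        if min(self.n_targets, self.n_compounds, self.n_decoys) < 1:
            raise ParameterError("counts must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    planted_pairs: frozenset[tuple[str, str]]   # (compound_id, pdb_id)
    planted_targets: tuple[str, ...]
    mapping: dict[str, str]                      # pdb_id -> uniprot_id


def compound_ids(spec: SyntheticPanelSpec) -> list[str]:
    return [f"c{i + 1}" for i in range(spec.n_compounds)]


def decoy_ids(spec: SyntheticPanelSpec) -> list[str]:
    return [f"d{i + 1:02d}" for i in range(spec.n_decoys)]


def target_ids(spec: SyntheticPanelSpec) -> list[str]:
    return [f"T{i + 1:03d}" for i in range(spec.n_targets)]


def generate_affinity_table(spec: SyntheticPanelSpec
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a recorded affinity table plus its ground-truth key.

    Planted targets are shared across all compounds (the screen's consensus
    logic expects true targets retrieved by every query).  Deterministic
    for a given spec: same seed, same table.
    """
    rng = np.random.default_rng(spec.seed)
    comps, decs, targs = compound_ids(spec), decoy_ids(spec), target_ids(spec)
    planted = tuple(targs[: spec.n_planted])
    rows = []
    for cid in comps:
        aff = rng.normal(spec.base_affinity_mean, spec.base_affinity_sd,
                         size=spec.n_targets)
        for j, tid in enumerate(targs):
            a = aff[j] + (spec.planted_shift if tid in planted else 0.0)
            rows.append((cid, tid, round(float(a), 3)))
    for did in decs:
        aff = rng.normal(spec.decoy_affinity_mean, spec.decoy_affinity_sd,
                         size=spec.n_targets)
        for j, tid in enumerate(targs):
            rows.append((did, tid, round(float(aff[j]), 3)))
    table = pd.DataFrame(rows, columns=["compound_id", "pdb_id",
                                        "affinity_kcal_mol"])
    mapping = {tid: f"U{int(tid[1:]):03d}" for tid in targs}
    key = GroundTruth(
        planted_pairs=frozenset((c, t) for c in comps for t in planted),
        planted_targets=planted,
        mapping=mapping,
    )
    return table, key


def write_affinity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_mapping(mapping: dict[str, str], path: str | Path,
                  names: dict[str, str] | None = None) -> None:
    names = names or {}
    pd.DataFrame(
        [{"pdb_id": k, "uniprot_id": v, "molecule_name": names.get(v, v)}
         for k, v in mapping.items()]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Toy receptor/ligand structures

@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a pseudo-protein shell with a carved cavity + toy ligand.

    The receptor is a ball of carbon pseudo-atoms on a 1.5 Å lattice with
    a spherical cavity opened to the surface by a channel along +z.  Atoms
    are written as one-atom pseudo-alanine residues (CA records) so that
    standard protein readers and filters accept the file; the construction
    tests geometry and plumbing, not chemistry.
    """

    cavity_radius: float = 4.0        # Å
    shell_thickness: float = 6.0      # Å of wall below the cavity
    ligand_size: int = 6              # heavy atoms
    seed: int = 0

    @property
    def protein_radius(self) -> float:
        return self.cavity_radius + self.shell_thickness + 2.0

    @property
    def cavity_center(self) -> tuple[float, float, float]:
        # cavity sits off-center so the channel to the surface is short
        return (0.0, 0.0, self.protein_radius - self.cavity_radius - 2.0)


_LATTICE = 1.5  # Å; dense enough that no interior gap counts as a cavity


def toy_receptor_coords(spec: ToyComplexSpec) -> np.ndarray:
    """Deterministic pseudo-atom coordinates for the cavity construction."""
    R = spec.protein_radius
    n = int(np.ceil(R / _LATTICE))
    axis = np.arange(-n, n + 1) * _LATTICE
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    inside = np.linalg.norm(pts, axis=1) <= R
    pts = pts[inside]
    cav = np.asarray(spec.cavity_center)
    in_cavity = np.linalg.norm(pts - cav, axis=1) <= spec.cavity_radius
    # channel: open the cavity to the surface along +z
    lateral = np.linalg.norm(pts[:, :2] - cav[:2], axis=1)
    in_channel = (lateral <= 1.8) & (pts[:, 2] >= cav[2])
    return pts[~(in_cavity | in_channel)]


def convex_receptor_coords(radius: float = 8.0) -> np.ndarray:
    """A solid convex lattice ball: the no-pocket negative control."""
    n = int(np.ceil(radius / _LATTICE))
    axis = np.arange(-n, n + 1) * _LATTICE
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def coords_to_pdb(coords: np.ndarray) -> str:
    """Render pseudo-atom coordinates as PDB text (CA-only pseudo-alanines)."""
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{((i - 1) % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _toy_ligand_mol(spec: ToyComplexSpec):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    smiles = "C1CCCCC1" if spec.ligand_size >= 6 else "C1CCCC1"
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = spec.seed % (2**31 - 1) or 1
    AllChem.EmbedMolecule(mol, params)
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    rgyr = float(np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean()))
    if rgyr >= spec.cavity_radius:
        warnings.warn(
            f"toy ligand radius of gyration {rgyr:.1f} Å does not fit the "
            f"{spec.cavity_radius:.1f} Å cavity", stacklevel=2)
    # translate the ligand into the cavity
    shift = np.asarray(spec.cavity_center) - xyz.mean(axis=0)
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (p.x + shift[0], p.y + shift[1], p.z + shift[2]))
    mol.SetProp("_Name", "toy_ligand")
    return mol


def generate_toy_complex(spec: ToyComplexSpec, out_dir: str | Path
                         ) -> tuple[Path, Path, tuple[float, float, float]]:
    """Write receptor PDB + ligand SDF; return paths and the cavity center.

    Byte-identical output for a fixed spec (the only randomness is the
    seeded conformer embedding).
    """
    from rdkit import Chem

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / "toy_receptor.pdb"
    sdf_path = out / "toy_ligand.sdf"
    pdb_path.write_text(coords_to_pdb(toy_receptor_coords(spec)))
    mol = _toy_ligand_mol(spec)
    with Chem.SDWriter(str(sdf_path)) as w:
        w.write(mol)
    return pdb_path, sdf_path, spec.cavity_center


# ---------------------------------------------------------------------------
# Decoy candidate libraries

def _polyol_smiles(n_carbons: int, n_oh: int, n_ether: int) -> str:
    """Linear alkyl chain with n_oh hydroxyls and n_ether interior ethers."""
    if n_carbons < max(3, n_ether + 2):
        n_carbons = max(3, n_ether + 2)
    runs = n_ether + 1
    base, extra = divmod(n_carbons, runs)
    segments = ["C" * (base + (1 if i < extra else 0)) for i in range(runs)]
    body = "O".join(segments)
    smiles = body
    if n_oh >= 1:
        smiles = "O" + smiles
    if n_oh >= 2:
        smiles = smiles + "O"
    if n_oh >= 3:
        # branch hydroxyl on the middle carbon of the first segment
        seg = segments[0]
        mid = max(1, len(seg) // 2)
        branched = seg[:mid] + "C(O)" + seg[mid + 1:] if len(seg) > 1 else "C(O)"
        smiles = ("O" + "O".join([branched] + segments[1:]))
        if n_oh >= 2:
            smiles += "O"
    return smiles


def generate_decoy_library(
    query_mw: float, query_hbd: int, query_hba: int,
    n_candidates: int = 50, seed: int = 0,
) -> list["Compound"]:
    """Emit candidate decoys spanning the MW/HBD/HBA matching windows.

    The first dozen candidates are built to sit squarely inside the
    default windows (MW +-25 Da, HBD/HBA +-1) of the supplied query
    properties, guaranteeing that a ten-decoy selection succeeds whenever
    ``n_candidates >= 12``; later candidates scatter around and outside
    the windows so rejection paths are exercised too.  All candidates are
    aliphatic polyol/polyether chains — structurally nothing like a
    terpenophenolic query, so the dissimilarity test passes trivially.
    Deterministic per seed.
    """
    from rdkit.Chem import Descriptors
    from rdkit import Chem
    from .compounds import Compound

    if query_hbd < 1 or query_hba < 1 or query_mw <= 50:
        raise ParameterError("query property targets out of range")
    rng = np.random.default_rng(seed)
    out: list[Compound] = []
    k = 0
    attempts = 0
    while len(out) < n_candidates and attempts < n_candidates * 20:
        attempts += 1
        idx = len(out)
        if idx < 12:
            mw_offset = float(rng.uniform(-18, 18))
            hbd = query_hbd
            hba = query_hba
        else:
            mw_offset = float(rng.uniform(-60, 60))
            hbd = max(1, query_hbd + int(rng.integers(-2, 3)))
            hba = max(hbd, query_hba + int(rng.integers(-2, 3)))
        n_oh = min(hbd, 3)
        n_ether = max(0, hba - n_oh)
        target_mw = query_mw + mw_offset
        n_c = max(3, round((target_mw - 17.0 * n_oh - 16.0 * n_ether) / 14.0))
        smi = _polyol_smiles(n_c, n_oh, n_ether)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if idx < 12:
            # nudge chain length until MW is safely inside the window
            for _ in range(6):
                mw = Descriptors.MolWt(mol)
                if abs(mw - query_mw) <= 20.0:
                    break
                n_c += -1 if mw > query_mw else 1
                smi = _polyol_smiles(n_c, n_oh, n_ether)
                mol = Chem.MolFromSmiles(smi)
            else:
                continue
        k += 1
        out.append(Compound(id=f"dk{k:03d}", name=f"decoy candidate {k}",
                            structure=smi, role="decoy"))
    return out


def write_smiles(compounds, path: str | Path) -> None:
    lines = [f"{c.structure}\t{c.id}" for c in compounds]
    Path(path).write_text("\n".join(lines) + "\n")
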