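"""Compound registry: query molecules, molecular properties and decoy selection.

The screen's query set is three Cannabis sativa leaf cannabinoids —
2alpha-hydroxy-Delta(3,7)-cannabitriol (``cbt1``), cannabidiol (CBD) and
cannabidiolic acid (CBDA).  Their identities are validated against
unit-resolution positive-mode ESI-MS [M+H]+ values, so masses here are
*nominal*: integer sums of most-abundant-isotope mass numbers (C=12, H=1,
O=16), protonated m/z = nominal mass + 1.

Decoys calibrate non-specific binding: each query gets exactly ten
molecules matched on molecular weight and hydrogen-bond donor/acceptor
counts but structurally dissimilar (2D fingerprint Tanimoto below a
threshold), so that a target that binds *anything* scores well for the
decoys too and is discounted by the V = V0/VR normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator
from rdkit import RDLogger

from .errors import InsufficientDecoysError, StructureError

RDLogger.DisableLog("rdApp.*")

_PERIODIC = Chem.GetPeriodicTable()
_MORGAN = GetMorganGenerator(radius=2, fpSize=2048)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable structure: {smiles!r}")
    return mol


@dataclass(frozen=True)
class Compound:
    """A query or decoy molecule.

    ``structure`` is a SMILES string, stereo-annotated where the
    configuration is known; ``formula`` (Hill notation) is derived from it
    and kept redundantly for identity checks.
    """

    id: str
    name: str
    structure: str
    formula: str = ""
    role: str = "query"

    def __post_init__(self):
        mol = _parse(self.structure)
        derived = rdMolDescriptors.CalcMolFormula(mol)
        if not self.formula:
            object.__setattr__(self, "formula", derived)
        elif self.formula != derived:
            raise StructureError(
                f"compound {self.id!r}: declared formula {self.formula} "
                f"inconsistent with structure ({derived})"
            )

    @property
    def mol(self) -> Chem.Mol:
        return _parse(self.structure)


@dataclass(frozen=True)
class MolecularProperties:
    """Descriptors used for identity checks and decoy matching."""

    mw: float               # average molecular weight, Da
    nominal_mass: int       # integer nominal (most-abundant-isotope) mass, Da
    mz_protonated: int      # nominal [M+H]+, Da
    hbd: int                # N/O atoms bearing >= 1 hydrogen
    hba: int                # N/O atom count
    n_rot: int              # rotatable open-chain bonds


@dataclass(frozen=True)
class DecoySet:
    query_id: str
    decoys: tuple[Compound, ...]
    matching_windows: "MatchWindows"
    dissimilarity_threshold: float

    def verify(self, query: Compound) -> bool:
        """Re-audit the set against its own recorded constraints."""
        qp = compute_properties(query)
        for d in self.decoys:
            if not self.matching_windows.matches(qp, compute_properties(d)):
                return False
            if tanimoto(query, d) >= self.dissimilarity_threshold:
                return False
        return len(self.decoys) == len({d.id for d in self.decoys})


@dataclass(frozen=True)
class MatchWindows:
    """Property tolerances a decoy must satisfy relative to its query.

    Defaults: MW within +-25 Da, donor and acceptor counts within +-1 —
    tight enough that decoys genuinely resemble the query, loose enough
    that ten can be found in a modest candidate library.
    """

    mw: float = 25.0
    hbd: int = 1
    hba: int = 1

    def matches(self, query: MolecularProperties, cand: MolecularProperties) -> bool:
        return (
            abs(cand.mw - query.mw) <= self.mw
            and abs(cand.hbd - query.hbd) <= self.hbd
            and abs(cand.hba - query.hba) <= self.hba
        )


#: The bundled query set.  Stereocenters of compound 1 follow its assigned
#: (1R,2R,6R) configuration; CBD/CBDA carry their standard (1R,6R) centers.
QUERY_COMPOUNDS: tuple[Compound, ...] = (
    Compound(
        id="cbt1",
        name="2alpha-hydroxy-Delta(3,7)-cannabitriol",
        structure="CCCCCc1cc(O)c([C@@H]2[C@H](O)C(=C)CC[C@H]2C(C)=C)c(O)c1",
        formula="C21H30O3",
    ),
    Compound(
        id="cbd",
        name="cannabidiol",
        structure="CCCCCc1cc(O)c([C@@H]2C=C(C)CC[C@H]2C(=C)C)c(O)c1",
        formula="C21H30O2",
    ),
    Compound(
        id="cbda",
        name="cannabidiolic acid",
        structure="CCCCCc1cc(O)c([C@@H]2C=C(C)CC[C@H]2C(=C)C)c(O)c1C(=O)O",
        formula="C22H30O4",
    ),
)


def compute_properties(compound: Compound) -> MolecularProperties:
    """Compute the matching/identity descriptor block for one compound.

    Pure and deterministic: depends only on the structure string.
    """
    mol = compound.mol
    molh = Chem.AddHs(mol)
    nominal = sum(
        _PERIODIC.GetMostCommonIsotope(a.GetAtomicNum()) for a in molh.GetAtoms()
    )
    hbd = hba = 0
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hba += 1
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                hbd += 1
    return MolecularProperties(
        mw=Descriptors.MolWt(mol),
        nominal_mass=nominal,
        mz_protonated=nominal + 1,
        hbd=hbd,
        hba=hba,
        n_rot=rdMolDescriptors.CalcNumRotatableBonds(mol),
    )


def validate_identity(compound: Compound, expected_mz: int) -> bool:
    """True iff the computed nominal [M+H]+ equals the recorded ESI-MS peak."""
    return compute_properties(compound).mz_protonated == int(expected_mz)


def tanimoto(a: Compound, b: Compound) -> float:
    """Morgan (radius 2) fingerprint Tanimoto similarity."""
    from rdkit import DataStructs

    fa = _MORGAN.GetFingerprint(a.mol)
    fb = _MORGAN.GetFingerprint(b.mol)
    return DataStructs.TanimotoSimilarity(fa, fb)


def select_decoys(
    query: Compound,
    candidates: Sequence[Compound],
    n: int = 10,
    windows: MatchWindows | None = None,
    dissimilarity_threshold: float = 0.4,
) -> DecoySet:
    """Pick ``n`` property-matched, structure-dissimilar decoys for a query.

    Eligible candidates fall inside the MW/HBD/HBA windows and have
    Tanimoto similarity to the query strictly below the threshold (the
    query itself is always excluded: self-similarity is 1).  Selection is
    deterministic — eligible candidates sorted by |deltaMW| then id — and
    therefore invariant under permutation of the candidate list.

    Raises :class:`InsufficientDecoysError` when fewer than ``n`` qualify.
    """
    windows = windows or MatchWindows()
    qp = compute_properties(query)
    eligible: list[tuple[float, str, Compound]] = []
    for cand in candidates:
        if cand.id == query.id:
            continue
        cp = compute_properties(cand)
        if not windows.matches(qp, cp):
            continue
        if tanimoto(query, cand) >= dissimilarity_threshold:
            continue
        eligible.append((abs(cp.mw - qp.mw), cand.id, cand))
    if len(eligible) < n:
        raise InsufficientDecoysError(query.id, n, len(eligible))
    eligible.sort(key=lambda t: (t[0], t[1]))
    chosen = tuple(
        Compound(c.id, c.name, c.structure, c.formula, role="decoy")
        for _, _, c in eligible[:n]
    )
    return DecoySet(query.id, chosen, windows, dissimilarity_threshold)


# ---------------------------------------------------------------------------
# File I/O

def read_smiles(path: str | Path, role: str = "query") -> list[Compound]:
    """Read a .smi file: one record per line, SMILES then whitespace then id."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"mol{len(out) + 1}"
        out.append(Compound(id=cid, name=cid, structure=smiles, role=role))
    return out


def read_sdf(path: str | Path, role: str = "query") -> list[Compound]:
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise StructureError(f"unparseable SDF record #{i + 1} in {path}")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
        out.append(Compound(id=cid, name=cid, structure=Chem.MolToSmiles(mol), role=role))
    return out


def write_library_table(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write the property table as TSV (one row per compound)."""
    import pandas as pd

    rows = []
    for c in compounds:
        p = compute_properties(c)
        rows.append(
            dict(id=c.id, name=c.name, formula=c.formula, mw=round(p.mw, 2),
                 nominal_mass=p.nominal_mass, mz_protonated=p.mz_protonated,
                 hbd=p.hbd, hba=p.hba, n_rot=p.n_rot)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
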