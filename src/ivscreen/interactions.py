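"""Geometric audit of docking poses: H-bonds, pi-pi stacks, salt bridges.

A docked pose is only as believable as its contacts, so each retained pose
is screened against the receptor with explicit geometric criteria and the
contacts are reported with residue labels (``chain:ResnameNumber``, e.g.
``B:Ser60``) that can be checked against the known binding-site residues
of the target (e.g. a serine-protease catalytic triad His57/Asp102/Ser195,
or the Tyr119 pair lining a cytokine trimer interface).

Default criteria (configurable via :class:`ContactCutoffs`):

* hydrogen bond — donor–acceptor heavy-atom distance <= 3.5 Å, plus a
  D–H···A angle >= 120 deg whenever hydrogen positions exist (crystal
  structures usually lack them, so the distance-only test is the
  fallback);
* pi-pi stack — ring centroid distance <= 5.5 Å, classified *parallel*
  when the interplanar angle is <= 30 deg and *t_shaped* at 60–90 deg;
  intermediate tilts are not reported;
* salt bridge — charged-group centroid distance <= 4.0 Å between a
  formally charged ligand group and Arg/Lys (positive) or Asp/Glu
  (negative) side chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import TypingError
from .panel import ReceptorStructure

# ---------------------------------------------------------------------------
# Receptor atom typing (standard amino-acid donors/acceptors/rings)

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}
_CHARGED_GROUPS = {  # residue -> (atoms forming the charged group, sign)
    "ARG": (("NE", "NH1", "NH2"), +1),
    "LYS": (("NZ",), +1),
    "ASP": (("OD1", "OD2"), -1),
    "GLU": (("OE1", "OE2"), -1),
}


@dataclass(frozen=True)
class ContactCutoffs:
    hbond_distance: float = 3.5        # Å, donor–acceptor heavy atoms
    hbond_angle_min: float = 120.0     # deg, D–H···A when H present
    pistack_distance: float = 5.5      # Å, ring centroid–centroid
    parallel_max_angle: float = 30.0   # deg
    tshape_min_angle: float = 60.0     # deg
    salt_bridge_distance: float = 4.0  # Å, charged-group centroids


@dataclass(frozen=True)
class ContactAtom:
    owner: str          # "ligand" | "receptor"
    label: str          # residue label for receptor, atom label for ligand
    atom_name: str


@dataclass(frozen=True)
class HBondContact:
    donor: ContactAtom
    acceptor: ContactAtom
    distance: float                 # Å heavy-atom D···A
    angle: float | None = None      # deg D–H···A; None without hydrogens

    @property
    def residue_label(self) -> str:
        return self.donor.label if self.donor.owner == "receptor" else self.acceptor.label


@dataclass(frozen=True)
class PiStackContact:
    ligand_ring: tuple[int, ...]    # ligand atom indices
    residue_label: str
    centroid_distance: float        # Å
    interplanar_angle: float        # deg, in [0, 90]
    geometry: str                   # "parallel" | "t_shaped"


@dataclass(frozen=True)
class SaltBridgeContact:
    ligand_atoms: tuple[int, ...]
    residue_label: str
    distance: float                 # Å
    ligand_charge: int


@dataclass
class InteractionReport:
    compound_id: str
    pdb_id: str
    pose_rank: int
    hbonds: list[HBondContact] = field(default_factory=list)
    pistacks: list[PiStackContact] = field(default_factory=list)
    salt_bridges: list[SaltBridgeContact] = field(default_factory=list)
    known_site_residues_hit: list[str] = field(default_factory=list)

    def contacted_residues(self) -> set[str]:
        out = {h.residue_label for h in self.hbonds}
        out |= {p.residue_label for p in self.pistacks}
        out |= {s.residue_label for s in self.salt_bridges}
        return out


# ---------------------------------------------------------------------------
# Ligand pose container

@dataclass
class LigandPose:
    """A typed ligand pose: elements, coordinates and interaction flags.

    ``donors``/``acceptors`` are heavy-atom indices; ``donor_hydrogens``
    optionally maps a donor index to hydrogen coordinates for the angle
    test; ``rings`` lists aromatic rings as index tuples; ``charges`` maps
    atom index to formal charge.
    """

    elements: list[str]
    coords: np.ndarray
    donors: frozenset[int] = frozenset()
    acceptors: frozenset[int] = frozenset()
    rings: tuple[tuple[int, ...], ...] = ()
    donor_hydrogens: dict[int, np.ndarray] = field(default_factory=dict)
    charges: dict[int, int] = field(default_factory=dict)
    atom_names: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise TypingError("pose coordinates do not match element list")
        if not all(e for e in self.elements):
            raise TypingError("pose atoms lack element symbols")

    def name_of(self, i: int) -> str:
        if self.atom_names:
            return self.atom_names[i]
        return f"{self.elements[i]}{i + 1}"

    @classmethod
    def from_rdkit(cls, mol) -> "LigandPose":
        """Type a pose from an RDKit molecule carrying a 3D conformer."""
        from rdkit import Chem

        if mol.GetNumConformers() == 0:
            raise TypingError("RDKit molecule has no conformer")
        conf = mol.GetConformer()
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        remap = {idx: i for i, idx in enumerate(heavy)}
        coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
        elements = [mol.GetAtomWithIdx(i).GetSymbol() for i in heavy]
        donors, acceptors, charges = set(), set(), {}
        donor_h: dict[int, list] = {}
        for idx in heavy:
            a = mol.GetAtomWithIdx(idx)
            if a.GetAtomicNum() in (7, 8):
                acceptors.add(remap[idx])
                if a.GetTotalNumHs(includeNeighbors=True) > 0:
                    donors.add(remap[idx])
                    for nb in a.GetNeighbors():
                        if nb.GetAtomicNum() == 1:
                            donor_h.setdefault(remap[idx], []).append(
                                list(conf.GetAtomPosition(nb.GetIdx())))
            if a.GetFormalCharge():
                charges[remap[idx]] = a.GetFormalCharge()
        rings = []
        ri = mol.GetRingInfo()
        for ring in ri.AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                rings.append(tuple(remap[i] for i in ring))
        return cls(
            elements=elements, coords=coords,
            donors=frozenset(donors), acceptors=frozenset(acceptors),
            rings=tuple(rings),
            donor_hydrogens={k: np.asarray(v) for k, v in donor_h.items()},
            charges=charges,
        )

    @classmethod
    def from_sdf(cls, path: str | Path) -> "LigandPose":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        mol = next(iter(supplier), None)
        if mol is None:
            raise TypingError(f"unreadable SDF pose: {path}")
        return cls.from_rdkit(mol)


# ---------------------------------------------------------------------------
# Residue labelling

def residue_label(chain: str, res_name: str, res_id: int) -> str:
    return f"{chain}:{str(res_name).capitalize()}{int(res_id)}"


def normalize_label(label: str) -> str:
    """Normalize a residue label for comparison: drop chain, lower-case.

    Reference lists often omit the chain (``Ser60`` vs ``B:Ser60``); both
    normalize to ``ser60``.
    """
    tail = label.split(":")[-1].strip()
    return tail.lower()


# ---------------------------------------------------------------------------
# Detection

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _receptor_atoms(receptor: ReceptorStructure, table: dict[str, set]) -> list:
    """(coord, label, atom_name) for typed side-chain atoms + backbone."""
    arr = receptor.atoms
    out = []
    for i in range(arr.array_length()):
        rn = str(arr.res_name[i]).upper()
        an = str(arr.atom_name[i]).upper()
        lab = residue_label(arr.chain_id[i], arr.res_name[i], arr.res_id[i])
        if an in table.get(rn, ()):  # side-chain
            out.append((arr.coord[i], lab, an))
        elif table is _SIDECHAIN_DONORS and an == "N" and rn != "PRO":
            out.append((arr.coord[i], lab, an))
        elif table is _SIDECHAIN_ACCEPTORS and an == "O":
            out.append((arr.coord[i], lab, an))
    return out


def detect_hbonds(pose: LigandPose, receptor: ReceptorStructure,
                  cutoffs: ContactCutoffs = ContactCutoffs()) -> list[HBondContact]:
    """All ligand–receptor donor/acceptor pairs within the H-bond windows.

    Both directions are scanned: ligand donor -> receptor acceptor (with
    the D–H···A angle test when the pose carries hydrogens) and receptor
    donor -> ligand acceptor (distance-only: receptor hydrogens are
    normally absent).  Sorted by distance.
    """
    rec_acc = _receptor_atoms(receptor, _SIDECHAIN_ACCEPTORS)
    rec_don = _receptor_atoms(receptor, _SIDECHAIN_DONORS)
    contacts: list[HBondContact] = []
    # a shared O-H...O pair is one bond: never report both directions
    seen: set[tuple[str, str, str]] = set()

    for d in sorted(pose.donors):
        dpos = pose.coords[d]
        for apos, lab, an in rec_acc:
            dist = float(np.linalg.norm(dpos - apos))
            if dist > cutoffs.hbond_distance:
                continue
            angle = None
            if d in pose.donor_hydrogens:
                angles = [_angle_deg(dpos, h, apos) for h in pose.donor_hydrogens[d]]
                angle = max(angles)
                if angle < cutoffs.hbond_angle_min:
                    continue
            seen.add((pose.name_of(d), lab, an))
            contacts.append(HBondContact(
                donor=ContactAtom("ligand", pose.name_of(d), pose.name_of(d)),
                acceptor=ContactAtom("receptor", lab, an),
                distance=dist, angle=angle,
            ))
    for a in sorted(pose.acceptors):
        apos = pose.coords[a]
        for dpos, lab, an in rec_don:
            dist = float(np.linalg.norm(apos - dpos))
            if dist > cutoffs.hbond_distance:
                continue
            if (pose.name_of(a), lab, an) in seen:
                continue
            contacts.append(HBondContact(
                donor=ContactAtom("receptor", lab, an),
                acceptor=ContactAtom("ligand", pose.name_of(a), pose.name_of(a)),
                distance=dist, angle=None,
            ))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def _ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # plane normal = smallest-variance principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[-1]


def receptor_rings(receptor: ReceptorStructure) -> list[tuple[str, np.ndarray]]:
    """(residue label, ring coordinates) for His/Phe/Tyr/Trp side chains."""
    arr = receptor.atoms
    out = []
    keys = sorted(set(zip(arr.chain_id, arr.res_id, arr.res_name)),
                  key=lambda k: (str(k[0]), int(k[1])))
    for chain, res_id, res_name in keys:
        rn = str(res_name).upper()
        if rn not in _AROMATIC_RINGS:
            continue
        mask = (arr.chain_id == chain) & (arr.res_id == res_id) & (arr.res_name == res_name)
        sub = arr[mask]
        names = [str(n).upper() for n in sub.atom_name]
        for ring_atoms in _AROMATIC_RINGS[rn]:
            try:
                idx = [names.index(a) for a in ring_atoms]
            except ValueError:
                continue  # incomplete side chain
            out.append((residue_label(chain, res_name, res_id), sub.coord[idx]))
    return out


def classify_ring_pair(coords_a: np.ndarray, coords_b: np.ndarray,
                       cutoffs: ContactCutoffs = ContactCutoffs()
                       ) -> tuple[float, float, str | None]:
    """(centroid distance, interplanar angle, geometry-or-None) for two rings.

    Symmetric in its arguments.
    """
    ca, na = _ring_centroid_normal(np.asarray(coords_a, dtype=float))
    cb, nb = _ring_centroid_normal(np.asarray(coords_b, dtype=float))
    dist = float(np.linalg.norm(ca - cb))
    cosang = abs(float(np.dot(na, nb)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    geometry = None
    if dist <= cutoffs.pistack_distance:
        if angle <= cutoffs.parallel_max_angle:
            geometry = "parallel"
        elif cutoffs.tshape_min_angle <= angle <= 90.0:
            geometry = "t_shaped"
    return dist, angle, geometry


def detect_pistacks(pose: LigandPose, receptor: ReceptorStructure,
                    cutoffs: ContactCutoffs = ContactCutoffs()
                    ) -> list[PiStackContact]:
    """Ligand-ring / receptor-ring stacks within the distance+angle windows."""
    contacts = []
    rings = receptor_rings(receptor)
    for lring in pose.rings:
        lcoords = pose.coords[list(lring)]
        for lab, rcoords in rings:
            dist, angle, geom = classify_ring_pair(lcoords, rcoords, cutoffs)
            if geom is None:
                continue
            contacts.append(PiStackContact(
                ligand_ring=tuple(lring), residue_label=lab,
                centroid_distance=dist, interplanar_angle=angle, geometry=geom,
            ))
    contacts.sort(key=lambda c: c.centroid_distance)
    return contacts


def detect_salt_bridges(pose: LigandPose, receptor: ReceptorStructure,
                        cutoffs: ContactCutoffs = ContactCutoffs()
                        ) -> list[SaltBridgeContact]:
    """Opposite formal charges with group-centroid distance <= 4.0 Å."""
    arr = receptor.atoms
    contacts = []
    keys = sorted(set(zip(arr.chain_id, arr.res_id, arr.res_name)),
                  key=lambda k: (str(k[0]), int(k[1])))
    groups = []
    for chain, res_id, res_name in keys:
        rn = str(res_name).upper()
        if rn not in _CHARGED_GROUPS:
            continue
        atoms, sign = _CHARGED_GROUPS[rn]
        mask = (arr.chain_id == chain) & (arr.res_id == res_id) & (arr.res_name == res_name)
        sub = arr[mask]
        names = [str(n).upper() for n in sub.atom_name]
        idx = [names.index(a) for a in atoms if a in names]
        if not idx:
            continue
        groups.append((residue_label(chain, res_name, res_id),
                       sub.coord[idx].mean(axis=0), sign))
    # ligand charged groups: single charged atoms (carboxylate O-, ammonium N+)
    for i, q in pose.charges.items():
        if q == 0:
            continue
        for lab, centroid, sign in groups:
            if sign * q >= 0:
                continue
            dist = float(np.linalg.norm(pose.coords[i] - centroid))
            if dist <= cutoffs.salt_bridge_distance:
                contacts.append(SaltBridgeContact(
                    ligand_atoms=(i,), residue_label=lab,
                    distance=dist, ligand_charge=q,
                ))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def score_known_site(report: InteractionReport,
                     reference_residues: Sequence[str]) -> list[str]:
    """Contacted residues that appear in a known binding-site list.

    Labels are normalized (chain stripped, case-folded) on both sides, so
    ``Ser60`` in a literature list matches a contact on ``B:Ser60``.
    Returns the matching contact labels sorted, and stores them on the
    report.
    """
    ref = {normalize_label(r) for r in reference_residues}
    hit = sorted(lab for lab in report.contacted_residues()
                 if normalize_label(lab) in ref)
    report.known_site_residues_hit = hit
    return hit


def audit_pose(pose: LigandPose, receptor: ReceptorStructure,
               compound_id: str = "", pdb_id: str = "", pose_rank: int = 1,
               cutoffs: ContactCutoffs = ContactCutoffs(),
               reference_residues: Sequence[str] = ()) -> InteractionReport:
    """Full contact report for one pose against one receptor."""
    report = InteractionReport(
        compound_id=compound_id, pdb_id=pdb_id or receptor.pdb_id,
        pose_rank=pose_rank,
        hbonds=detect_hbonds(pose, receptor, cutoffs),
        pistacks=detect_pistacks(pose, receptor, cutoffs),
        salt_bridges=detect_salt_bridges(pose, receptor, cutoffs),
    )
    if reference_residues:
        score_known_site(report, reference_residues)
    return report


def write_contacts_tsv(report: InteractionReport, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for h in report.hbonds:
        rows.append({"class": "hbond", "ligand_atom": h.donor.atom_name
                     if h.donor.owner == "ligand" else h.acceptor.atom_name,
                     "residue_label": h.residue_label,
                     "distance": round(h.distance, 3),
                     "angle": None if h.angle is None else round(h.angle, 1),
                     "geometry": ""})
    for p in report.pistacks:
        rows.append({"class": "pi_stack",
                     "ligand_atom": "+".join(str(i) for i in p.ligand_ring),
                     "residue_label": p.residue_label,
                     "distance": round(p.centroid_distance, 3),
                     "angle": round(p.interplanar_angle, 1),
                     "geometry": p.geometry})
    for s in report.salt_bridges:
        rows.append({"class": "salt_bridge",
                     "ligand_atom": "+".join(str(i) for i in s.ligand_atoms),
                     "residue_label": s.residue_label,
                     "distance": round(s.distance, 3),
                     "angle": None, "geometry": ""})
    pd.DataFrame(rows, columns=["class", "ligand_atom", "residue_label",
                                "distance", "angle", "geometry"]
                 ).to_csv(path, sep="\t", index=False)
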