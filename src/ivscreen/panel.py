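"""Target-panel preparation: structure cleaning, binding sites, docking boxes.

Panel structures arrive as PDB files annotated to a UniProt accession.
Preparation mirrors a standard receptor-prep workflow: strip waters, ions
and crystallization additives; keep the first model of multi-model
(NMR-style) entries and the highest-occupancy alternate location; pull any
remaining drug-like hetero group aside as the co-crystallized ligand.  The
binding site is then either mapped around that ligand or, for apo
structures, detected by a grid buriedness scan (:mod:`ivscreen.pockets`).
The docking search volume adds a 10 Å buffer per direction around the site
bounding box; the 1.0 Å grid spacing is recorded as metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdbio

from .errors import DegenerateLigandError, DegenerateStructureError, ParameterError

log = logging.getLogger(__name__)

#: Residue names removed during cleaning: water, common ions, cryoprotectants
#: and buffer components.  User-extensible via ``clean_structure(extra=...)``.
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset({
    "HOH", "DOD", "WAT",
    "NA", "K", "CL", "BR", "IOD", "F", "MG", "CA", "ZN", "MN", "FE", "FE2",
    "CU", "NI", "CO", "CD", "HG", "SR", "CS", "LI", "RB", "BA", "AL",
    "SO4", "PO4", "NO3", "CO3", "ACT", "FMT", "CIT", "TLA", "MLI", "OXL",
    "GOL", "EDO", "PEG", "PGE", "PG4", "P6G", "1PE", "MPD", "BME", "DTT",
    "DMS", "EOH", "MOH", "IPA", "ACE", "NH2", "TRS", "EPE", "MES", "BCT",
    "AZI", "SCN", "NH4", "IMD",
})


@dataclass
class ReceptorStructure:
    """A cleaned protein model plus the audit trail of what was removed."""

    pdb_id: str
    atoms: struc.AtomArray                    # protein (and kept cofactor) atoms
    removed: list[dict] = field(default_factory=list)
    cocrystal_ligand: struc.AtomArray | None = None

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()


@dataclass(frozen=True)
class BindingSite:
    center: tuple[float, float, float]        # Å
    bounding_box: tuple[tuple[float, float, float], tuple[float, float, float]]
    score: float
    provenance: str                            # "ligand_derived" | "detected"

    @property
    def extent(self) -> np.ndarray:
        lo, hi = np.asarray(self.bounding_box[0]), np.asarray(self.bounding_box[1])
        return hi - lo


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float]        # Å
    size: tuple[float, float, float]          # Å per axis
    buffer: float = 10.0                       # Å added on each face
    spacing: float = 1.0                       # Å between grid points (metadata)

    def contains(self, point) -> bool:
        c, s = np.asarray(self.center), np.asarray(self.size)
        return bool(np.all(np.abs(np.asarray(point) - c) <= s / 2 + 1e-9))


def _load_pdb(source: str | Path) -> pdbio.PDBFile:
    import io

    s = str(source)
    if isinstance(source, Path) or ("\n" not in s and len(s) < 4096):
        text = Path(s).read_text()
    else:  # raw PDB text
        text = s
    return pdbio.PDBFile.read(io.StringIO(text))


def clean_structure(
    raw_pdb: str | Path,
    exclusion_list: frozenset[str] | set[str] = DEFAULT_EXCLUSIONS,
    pdb_id: str = "",
) -> ReceptorStructure:
    """Clean one PDB entry into a docking-ready receptor.

    ``raw_pdb`` may be a path or raw PDB text.  Model 1 is kept for
    multi-model files and the highest-occupancy altloc per atom group.
    Excluded residues (waters, ions, buffer) are removed and logged; the
    largest remaining hetero group is extracted as ``cocrystal_ligand``.

    Cleaning is idempotent: feeding a cleaned structure back through
    changes nothing.

    Raises :class:`DegenerateStructureError` if no protein atoms survive.
    """
    pdbf = _load_pdb(raw_pdb)
    arr = pdbio.get_structure(
        pdbf, model=1, altloc="occupancy", extra_fields=["occupancy"]
    )
    if not pdb_id:
        pdb_id = "UNKNOWN"

    removed: list[dict] = []
    excl = frozenset(r.upper() for r in exclusion_list)
    drop = np.isin(np.char.upper(arr.res_name.astype("U4")), sorted(excl))
    if drop.any():
        for chain, res_id, res_name in sorted(
            set(zip(arr.chain_id[drop], arr.res_id[drop], arr.res_name[drop]))
        ):
            removed.append(
                {"chain": str(chain), "res_id": int(res_id),
                 "res_name": str(res_name), "reason": "excluded"}
            )
    arr = arr[~drop]

    # Split remaining hetero groups; largest (most heavy atoms) is "the ligand".
    hetero_mask = arr.hetero
    ligand = None
    if hetero_mask.any():
        het = arr[hetero_mask]
        groups: dict[tuple, int] = {}
        heavy = het.element != "H"
        for key in zip(het.chain_id, het.res_id, het.res_name):
            groups.setdefault(key, 0)
        for key, h in zip(zip(het.chain_id, het.res_id, het.res_name), heavy):
            groups[key] += int(h)
        # deterministic: most heavy atoms first, ties by (chain, res_id)
        best = sorted(groups.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))[0][0]
        lig_mask = (
            (arr.chain_id == best[0]) & (arr.res_id == best[1]) & (arr.res_name == best[2])
        )
        ligand = arr[lig_mask]
        arr = arr[~lig_mask]

    protein = arr[struc.filter_amino_acids(arr)]
    if protein.array_length() == 0:
        raise DegenerateStructureError(
            f"{pdb_id}: no protein atoms remain after cleaning"
        )
    if not np.all(np.isfinite(arr.coord)):
        raise DegenerateStructureError(f"{pdb_id}: non-finite coordinates")
    return ReceptorStructure(pdb_id=pdb_id, atoms=arr, removed=removed,
                             cocrystal_ligand=ligand)


def site_from_ligand(receptor: ReceptorStructure) -> BindingSite:
    """Map the binding site from the co-crystallized ligand's heavy atoms.

    Center = heavy-atom centroid; bounding box = axis-aligned heavy-atom
    bounds.  Requires at least 3 heavy atoms — a stray single-atom ion is
    not a site.
    """
    lig = receptor.cocrystal_ligand
    if lig is None:
        raise DegenerateLigandError(f"{receptor.pdb_id}: no co-crystallized ligand")
    heavy = lig[lig.element != "H"]
    if heavy.array_length() < 3:
        raise DegenerateLigandError(
            f"{receptor.pdb_id}: ligand has {heavy.array_length()} heavy atoms (< 3)"
        )
    lo = heavy.coord.min(axis=0)
    hi = heavy.coord.max(axis=0)
    center = heavy.coord.mean(axis=0)
    return BindingSite(
        center=tuple(float(x) for x in center),
        bounding_box=(tuple(float(x) for x in lo), tuple(float(x) for x in hi)),
        score=float(heavy.array_length()),
        provenance="ligand_derived",
    )


def build_box(site: BindingSite, buffer: float = 10.0, spacing: float = 1.0) -> DockingBox:
    """Expand a binding site into the docking search volume.

    Per-axis size = site extent + 2 x buffer, so the box always contains
    the site bounding box with at least ``buffer`` margin on every face.
    """
    if buffer <= 0:
        raise ParameterError(f"buffer must be positive, got {buffer}")
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    lo = np.asarray(site.bounding_box[0], dtype=float)
    hi = np.asarray(site.bounding_box[1], dtype=float)
    size = (hi - lo) + 2.0 * buffer
    center = (hi + lo) / 2.0
    return DockingBox(
        center=tuple(float(x) for x in center),
        size=tuple(float(x) for x in size),
        buffer=float(buffer),
        spacing=float(spacing),
    )


def define_site(receptor: ReceptorStructure) -> BindingSite:
    """Dispatch rule: ligand-derived site if a ligand exists, else detection.

    For apo structures the buriedness scan's top-ranked pocket is used; if
    no pocket is found the geometric center of the protein is a last-resort
    fallback (logged).
    """
    from .pockets import detect_binding_site

    if receptor.cocrystal_ligand is not None:
        try:
            return site_from_ligand(receptor)
        except DegenerateLigandError:
            log.warning("%s: degenerate ligand, falling back to detection",
                        receptor.pdb_id)
    sites = detect_binding_site(receptor)
    if sites:
        return sites[0]
    log.warning("%s: no pocket detected; using protein centroid", receptor.pdb_id)
    coord = receptor.atoms.coord
    c = coord.mean(axis=0)
    return BindingSite(tuple(map(float, c)),
                       (tuple(map(float, c - 5)), tuple(map(float, c + 5))),
                       score=0.0, provenance="detected")


def write_receptor_pdb(receptor: ReceptorStructure, path: str | Path) -> None:
    f = pdbio.PDBFile()
    pdbio.set_structure(f, receptor.atoms)
    f.write(str(path))


def write_site_sidecar(pdb_id: str, site: BindingSite, box: DockingBox,
                       path: str | Path) -> None:
    payload = {
        "pdb_id": pdb_id,
        "site": {"center": site.center, "bounding_box": site.bounding_box,
                 "score": site.score, "provenance": site.provenance},
        "box": {"center": box.center, "size": box.size,
                "buffer": box.buffer, "spacing": box.spacing},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a pdb_id -> uniprot_id mapping TSV (header optional)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "pdb_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["pdb_id", "uniprot_id", "molecule_name"])
    return dict(zip(df["pdb_id"], df["uniprot_id"]))


def prepare_panel(
    pdb_dir: str | Path,
    exclusion_list: frozenset[str] = DEFAULT_EXCLUSIONS,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, tuple[ReceptorStructure, BindingSite, DockingBox]], list[dict]]:
    """Prepare every ``*.pdb`` entry in a directory; skip-and-log failures.

    Returns (prepared, failures) — a failed entry never aborts the run.
    """
    prepared = {}
    failures = []
    for path in sorted(Path(pdb_dir).glob("*.pdb")):
        pdb_id = path.stem
        try:
            rec = clean_structure(path, exclusion_list, pdb_id=pdb_id)
            site = define_site(rec)
            box = build_box(site)
        except Exception as exc:  # fault-tolerance contract
            log.warning("panel entry %s failed: %s", pdb_id, exc)
            failures.append({"pdb_id": pdb_id, "error": str(exc)})
            continue
        prepared[pdb_id] = (rec, site, box)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_receptor_pdb(rec, out / f"{pdb_id}_clean.pdb")
            write_site_sidecar(pdb_id, site, box, out / f"{pdb_id}_site.json")
    return prepared, failures
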