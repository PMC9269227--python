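"""Docking execution layer: engine contract, Vina adapter and replay mode.

Downstream analysis only consumes best-pose affinities (kcal/mol, more
negative = stronger), so the engine is pluggable behind a tiny contract:
``backend.dock(job) -> DockingRecord``.  Two backends ship:

* :class:`VinaBackend` — drives an AutoDock-Vina-compatible executable via
  subprocess using the conventional flags (receptor/ligand PDBQT, box
  center and size, ``--exhaustiveness`` 64 by default, ``--seed``).
  Ligand and receptor preparation to PDBQT (3D coordinates, hydrogens at
  pH 7.4, rotatable-bond typing) is delegated to the Open Babel ``obabel``
  converter; all open-chain single bonds are treated as active torsions.
* :class:`ReplayBackend` — serves affinities from a recorded table
  (compound_id, pdb_id, affinity_kcal_mol).  Replay is bit-reproducible
  and makes every downstream stage testable with no docking engine
  installed; it is also how published affinity tables are re-analyzed.

Batch execution is fault-tolerant: a failed job is logged and recorded,
never fatal, unless *every* job fails.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import BatchError, EngineError
from .panel import DockingBox

log = logging.getLogger(__name__)

DEFAULT_EXHAUSTIVENESS = 64
DEFAULT_SEED = 20220624   # fixed so repeated runs agree; recorded in engine_meta


@dataclass(frozen=True)
class DockingJob:
    compound_id: str
    pdb_id: str
    box: DockingBox
    exhaustiveness: int = DEFAULT_EXHAUSTIVENESS
    seed: int | None = DEFAULT_SEED
    # all open-chain single bonds are active torsions; recorded for provenance
    torsion_policy: str = "all_open_chain_active"

    def __post_init__(self):
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


@dataclass(frozen=True)
class DockingPose:
    coordinates: tuple       # ligand atom coordinates, Å (may be empty in replay)
    affinity: float          # kcal/mol
    rank: int                # 1 = best


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    pdb_id: str
    best_affinity: float     # V0 for normalization, kcal/mol
    poses: tuple[DockingPose, ...] = ()
    engine_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.poses:
            best = min(p.affinity for p in self.poses)
            if abs(best - self.best_affinity) > 1e-9:
                raise ValueError("best_affinity must equal the minimum pose affinity")


class DockingBackend(Protocol):
    def dock(self, job: DockingJob) -> DockingRecord: ...


# ---------------------------------------------------------------------------
# Replay backend

class ReplayBackend:
    """Serve recorded best affinities for (compound, structure) pairs.

    The table is a DataFrame or TSV with columns
    ``compound_id, pdb_id, affinity_kcal_mol``.
    """

    name = "replay"

    def __init__(self, table: pd.DataFrame | str | Path):
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", dtype={"compound_id": str, "pdb_id": str})
        required = {"compound_id", "pdb_id", "affinity_kcal_mol"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"recorded table missing columns: {sorted(missing)}")
        self._index: dict[tuple[str, str], float] = {
            (str(r.compound_id), str(r.pdb_id)): float(r.affinity_kcal_mol)
            for r in table.itertuples()
        }

    def dock(self, job: DockingJob) -> DockingRecord:
        key = (job.compound_id, job.pdb_id)
        if key not in self._index:
            raise EngineError("no recorded affinity", *key)
        aff = self._index[key]
        return DockingRecord(
            compound_id=job.compound_id,
            pdb_id=job.pdb_id,
            best_affinity=aff,
            poses=(DockingPose(coordinates=(), affinity=aff, rank=1),),
            engine_meta={"engine": "replay", "seed": job.seed},
        )


# ---------------------------------------------------------------------------
# Vina-compatible subprocess backend

_AFFINITY_LINE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s")


def prepare_ligand_pdbqt(smiles: str, out_path: str | Path,
                         obabel: str = "obabel") -> Path:
    """SMILES -> 3D ligand PDBQT via Open Babel (hydrogens at pH 7.4).

    Open Babel assigns Gasteiger charges and flags all open-chain single
    bonds as active torsions, matching the screen's torsion policy.
    """
    out_path = Path(out_path)
    cmd = [obabel, f"-:{smiles}", "-opdbqt", "-O", str(out_path),
           "--gen3d", "-p", "7.4"]
    res = subprocess.run(cmd, capture_output=True, text=True)
    if res.returncode != 0 or not out_path.exists():
        raise EngineError(f"obabel ligand preparation failed: {res.stderr.strip()}")
    return out_path


def prepare_receptor_pdbqt(pdb_path: str | Path, out_path: str | Path,
                           obabel: str = "obabel") -> Path:
    """Cleaned receptor PDB -> rigid receptor PDBQT via Open Babel."""
    out_path = Path(out_path)
    cmd = [obabel, str(pdb_path), "-opdbqt", "-O", str(out_path), "-xr", "-p", "7.4"]
    res = subprocess.run(cmd, capture_output=True, text=True)
    if res.returncode != 0 or not out_path.exists():
        raise EngineError(f"obabel receptor preparation failed: {res.stderr.strip()}")
    return out_path


class VinaBackend:
    """Subprocess adapter for an AutoDock-Vina-compatible executable.

    ``ligands`` maps compound_id -> ligand PDBQT path and ``receptors``
    maps pdb_id -> receptor PDBQT path; preparation helpers above produce
    them.  The engine is invoked per job with the job's box, exhaustiveness
    and seed, and the pose table parsed from stdout/output file.
    """

    name = "vina"

    def __init__(self, ligands: dict[str, Path], receptors: dict[str, Path],
                 executable: str = "vina", timeout: float = 1800.0):
        self.ligands = {k: Path(v) for k, v in ligands.items()}
        self.receptors = {k: Path(v) for k, v in receptors.items()}
        self.executable = executable
        self.timeout = timeout

    @staticmethod
    def available(executable: str = "vina") -> bool:
        return shutil.which(executable) is not None

    def command(self, job: DockingJob, ligand: Path, receptor: Path,
                out: Path) -> list[str]:
        cx, cy, cz = job.box.center
        sx, sy, sz = job.box.size
        cmd = [
            self.executable,
            "--receptor", str(receptor), "--ligand", str(ligand),
            "--center_x", f"{cx:.3f}", "--center_y", f"{cy:.3f}",
            "--center_z", f"{cz:.3f}",
            "--size_x", f"{sx:.3f}", "--size_y", f"{sy:.3f}", "--size_z", f"{sz:.3f}",
            "--exhaustiveness", str(job.exhaustiveness),
            "--out", str(out),
        ]
        if job.seed is not None:
            cmd += ["--seed", str(job.seed)]
        return cmd

    def dock(self, job: DockingJob) -> DockingRecord:
        ligand = self.ligands.get(job.compound_id)
        receptor = self.receptors.get(job.pdb_id)
        if ligand is None or not ligand.exists():
            raise EngineError("ligand file missing", job.compound_id, job.pdb_id)
        if receptor is None or not receptor.exists():
            raise EngineError("receptor file missing", job.compound_id, job.pdb_id)
        if not self.available(self.executable):
            raise EngineError(f"engine executable {self.executable!r} not found",
                              job.compound_id, job.pdb_id)
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(tmp) / "out.pdbqt"
            cmd = self.command(job, ligand, receptor, out)
            try:
                res = subprocess.run(cmd, capture_output=True, text=True,
                                     timeout=self.timeout)
            except subprocess.TimeoutExpired as exc:
                raise EngineError(f"engine timeout after {self.timeout}s",
                                  job.compound_id, job.pdb_id) from exc
            if res.returncode != 0:
                raise EngineError(f"engine exit {res.returncode}: "
                                  f"{res.stderr.strip()[:500]}",
                                  job.compound_id, job.pdb_id)
            affinities = [float(m.group(2)) for line in res.stdout.splitlines()
                          if (m := _AFFINITY_LINE.match(line))]
            pose_coords = _parse_pdbqt_models(out) if out.exists() else []
        if not affinities:
            raise EngineError("no pose affinities parsed from engine output",
                              job.compound_id, job.pdb_id)
        affinities.sort()
        poses = tuple(
            DockingPose(
                coordinates=tuple(map(tuple, pose_coords[i])) if i < len(pose_coords) else (),
                affinity=a, rank=i + 1,
            )
            for i, a in enumerate(affinities)
        )
        return DockingRecord(
            compound_id=job.compound_id, pdb_id=job.pdb_id,
            best_affinity=affinities[0], poses=poses,
            engine_meta={"engine": self.executable, "seed": job.seed,
                         "exhaustiveness": job.exhaustiveness},
        )


def _parse_pdbqt_models(path: Path) -> list[np.ndarray]:
    models, cur = [], []
    for line in path.read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            cur.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif line.startswith("ENDMDL") and cur:
            models.append(np.array(cur))
            cur = []
    if cur:
        models.append(np.array(cur))
    return models


# ---------------------------------------------------------------------------
# Batch driver

def dock(job: DockingJob, backend: DockingBackend) -> DockingRecord:
    """Run one docking job through a backend (thin alias for the contract)."""
    return backend.dock(job)


def dock_batch(
    jobs: Sequence[DockingJob], backend: DockingBackend
) -> tuple[list[DockingRecord], list[dict]]:
    """Run a batch; one record or one logged failure per job.

    Results are returned sorted by (compound_id, pdb_id), so they are
    invariant under job reordering.  Raises :class:`BatchError` only when
    every job failed.
    """
    if not jobs:
        raise BatchError("empty job list")
    records, failures = [], []
    for job in jobs:
        try:
            records.append(backend.dock(job))
        except EngineError as exc:
            log.warning("docking job failed: %s", exc)
            failures.append({"compound_id": job.compound_id,
                             "pdb_id": job.pdb_id, "error": str(exc)})
    if not records:
        raise BatchError(f"all {len(jobs)} docking jobs failed")
    records.sort(key=lambda r: (r.compound_id, r.pdb_id))
    return records, failures


def records_to_table(records: Sequence[DockingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"compound_id": r.compound_id, "pdb_id": r.pdb_id,
          "affinity_kcal_mol": r.best_affinity} for r in records]
    )
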