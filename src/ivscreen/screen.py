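"""Decoy-normalized inverse virtual screening analysis.

Inverse virtual screening docks a few query ligands against a large
protein panel and ranks the *targets*.  Raw docking affinities are biased
toward large greasy pockets that bind anything, so each (compound,
structure) best affinity V0 is normalized by VR, the arithmetic mean of
the best affinities of ten property-matched decoys on the same structure:

    V = V0 / VR

V is dimensionless; V > 1 means the query outperforms its decoys on that
target.  Hits are then retained only when both retention filters hold
strictly:

    V0 < -7.5 kcal/mol   (absolute affinity threshold, e_max)
    V  >  0.75           (normalized threshold, v_min)

and the surviving hits are summarized two ways: the top-scoring target per
compound (by raw affinity or by V), and the consensus targets — UniProt
accessions with at least one retained structure for *every* query
compound, ranked by how often they were retrieved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .docking import DockingBackend, DockingJob, DockingRecord, dock_batch
from .errors import NormalizationError

log = logging.getLogger(__name__)

DEFAULT_E_MAX = -7.5   # kcal/mol
DEFAULT_V_MIN = 0.75   # dimensionless


@dataclass(frozen=True)
class ScreenFilter:
    """Retention thresholds; both inequalities are strict."""

    e_max: float = DEFAULT_E_MAX   # keep V0 strictly below this, kcal/mol
    v_min: float = DEFAULT_V_MIN   # keep V strictly above this

    def __post_init__(self):
        if not self.e_max < 0:
            raise ValueError(f"e_max must be negative, got {self.e_max}")
        if not self.v_min > 0:
            raise ValueError(f"v_min must be positive, got {self.v_min}")


@dataclass(frozen=True)
class NormalizedHit:
    compound_id: str
    pdb_id: str
    uniprot_id: str
    V0: float        # best query affinity on this structure, kcal/mol
    VR: float        # mean best decoy affinity on this structure, kcal/mol
    V: float         # V0 / VR, dimensionless
    passed: bool = False


@dataclass(frozen=True)
class CompoundTopScore:
    compound_id: str
    by: str          # "affinity" | "V"
    pdb_id: str
    uniprot_id: str
    molecule_name: str
    value: float
    tie: bool = False


@dataclass(frozen=True)
class ConsensusTarget:
    uniprot_id: str
    molecule_name: str
    retrieval_count: int
    per_compound_best: dict[str, tuple[float, str]]  # compound -> (V0, pdb_id)


def normalize(V0: float, decoy_affinities: Sequence[float]) -> tuple[float, float]:
    """Form (VR, V) from a query affinity and its decoy affinities.

    VR is the plain arithmetic mean of all decoy best affinities — no
    trimming or outlier rejection.  A non-negative VR (decoys that on
    average do not bind) makes the ratio meaningless and raises
    :class:`NormalizationError`.
    """
    if not decoy_affinities:
        raise NormalizationError("no decoy affinities supplied")
    VR = fmean(decoy_affinities)
    if VR >= 0:
        raise NormalizationError(f"mean decoy affinity VR={VR:.3f} is not negative")
    return VR, V0 / VR


def normalize_records(
    query_records: Sequence[DockingRecord],
    decoy_records: Sequence[DockingRecord],
    decoy_ids_by_query: Mapping[str, Sequence[str]],
    mapping: Mapping[str, str],
) -> list[NormalizedHit]:
    """Join query and decoy docking records into normalized hits.

    ``decoy_ids_by_query`` names each query's decoy set; VR for a
    (query, structure) pair averages that query's decoys on that
    structure.  Pairs whose VR cannot be formed are logged and dropped.
    Queries with non-negative V0 are auto-failed (docking can emit
    non-binding scores) rather than erroring the run.
    """
    decoy_lookup: dict[tuple[str, str], float] = {
        (r.compound_id, r.pdb_id): r.best_affinity for r in decoy_records
    }
    hits: list[NormalizedHit] = []
    for rec in query_records:
        decoy_ids = decoy_ids_by_query.get(rec.compound_id, ())
        affs = [decoy_lookup[(d, rec.pdb_id)] for d in decoy_ids
                if (d, rec.pdb_id) in decoy_lookup]
        try:
            VR, V = normalize(rec.best_affinity, affs)
        except NormalizationError as exc:
            log.warning("hit (%s, %s) excluded: %s", rec.compound_id, rec.pdb_id, exc)
            continue
        hits.append(NormalizedHit(
            compound_id=rec.compound_id,
            pdb_id=rec.pdb_id,
            uniprot_id=mapping.get(rec.pdb_id, ""),
            V0=rec.best_affinity, VR=VR, V=V,
        ))
    return hits


def apply_filter(hits: Iterable[NormalizedHit],
                 filt: ScreenFilter = ScreenFilter()) -> list[NormalizedHit]:
    """Mark-and-keep hits satisfying both strict retention thresholds.

    Order is preserved.  A hit at exactly the threshold (V0 == e_max or
    V == v_min) is dropped.  Non-binding scores (V0 >= 0) always fail.
    """
    kept = []
    for h in hits:
        ok = (h.V0 < filt.e_max) and (h.V > filt.v_min) and h.V0 < 0
        if ok:
            kept.append(NormalizedHit(h.compound_id, h.pdb_id, h.uniprot_id,
                                      h.V0, h.VR, h.V, passed=True))
    return kept


def top_scores(
    hits: Sequence[NormalizedHit],
    by: str = "affinity",
    names: Mapping[str, str] | None = None,
) -> list[CompoundTopScore]:
    """The single best retained target per compound.

    ``by="affinity"`` takes the minimum V0; ``by="V"`` the maximum V.
    Ties break deterministically by lower V0 then lexicographic pdb_id and
    are flagged in the result.  Compounds with no retained hit are omitted
    with a warning.
    """
    if by not in ("affinity", "V"):
        raise ValueError(f"criterion must be 'affinity' or 'V', got {by!r}")
    names = names or {}
    out: list[CompoundTopScore] = []
    for cid in sorted({h.compound_id for h in hits}):
        chits = [h for h in hits if h.compound_id == cid]
        if by == "affinity":
            keyval = lambda h: h.V0
            best_val = min(h.V0 for h in chits)
            tied = [h for h in chits if h.V0 == best_val]
        else:
            best_val = max(h.V for h in chits)
            tied = [h for h in chits if h.V == best_val]
        winner = min(tied, key=lambda h: (h.V0, h.pdb_id))
        out.append(CompoundTopScore(
            compound_id=cid, by=by, pdb_id=winner.pdb_id,
            uniprot_id=winner.uniprot_id,
            molecule_name=names.get(winner.uniprot_id, ""),
            value=winner.V0 if by == "affinity" else winner.V,
            tie=len(tied) > 1,
        ))
    return out


def consensus_targets(
    hits: Sequence[NormalizedHit],
    mapping: Mapping[str, str] | None = None,
    names: Mapping[str, str] | None = None,
    compound_ids: Sequence[str] | None = None,
) -> list[ConsensusTarget]:
    """UniProt-grouped targets retained for every query compound.

    ``retrieval_count`` is the total number of retained (compound,
    structure) hits mapping to the accession; ``per_compound_best`` keeps
    each compound's minimum V0 and its structure.  Unmapped hits are
    excluded from consensus (with a warning) but nothing else.  Sorted by
    retrieval count descending, ties by best overall V0.
    """
    names = names or {}
    compound_ids = sorted(compound_ids or {h.compound_id for h in hits})
    groups: dict[str, list[NormalizedHit]] = {}
    for h in hits:
        uid = h.uniprot_id or (mapping or {}).get(h.pdb_id, "")
        if not uid:
            log.warning("hit (%s, %s): no UniProt mapping; excluded from consensus",
                        h.compound_id, h.pdb_id)
            continue
        groups.setdefault(uid, []).append(h)
    out: list[ConsensusTarget] = []
    for uid, ghits in groups.items():
        covered = {h.compound_id for h in ghits}
        if not set(compound_ids) <= covered:
            continue
        per_best: dict[str, tuple[float, str]] = {}
        for cid in compound_ids:
            chits = [h for h in ghits if h.compound_id == cid]
            best = min(chits, key=lambda h: (h.V0, h.pdb_id))
            per_best[cid] = (best.V0, best.pdb_id)
        out.append(ConsensusTarget(
            uniprot_id=uid, molecule_name=names.get(uid, ""),
            retrieval_count=len(ghits), per_compound_best=per_best,
        ))
    out.sort(key=lambda t: (-t.retrieval_count,
                            min(v for v, _ in t.per_compound_best.values()),
                            t.uniprot_id))
    return out


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class ScreenReport:
    """Versioned, fully provenance-stamped output of one screen."""

    version: str
    filter: dict
    engine_meta: dict
    n_query_records: int
    n_passed: int
    hits: list[NormalizedHit]
    passed: list[NormalizedHit]
    top_by_affinity: list[CompoundTopScore]
    top_by_V: list[CompoundTopScore]
    consensus: list[ConsensusTarget]
    warnings: list[str] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    # how "most retrieved" is counted; flagged because other readings exist
    retrieval_count_definition: str = "passed (compound, structure) hits per UniProt"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def top_scores_table(self) -> pd.DataFrame:
        rows = [asdict(t) for t in self.top_by_affinity + self.top_by_V]
        cols = ["compound_id", "by", "pdb_id", "uniprot_id", "molecule_name",
                "value", "tie"]
        return pd.DataFrame(rows, columns=cols)

    def consensus_table(self, compound_ids: Sequence[str] | None = None) -> pd.DataFrame:
        cids = compound_ids or sorted(
            {c for t in self.consensus for c in t.per_compound_best}
        )
        rows = []
        for t in self.consensus:
            row = {"uniprot_id": t.uniprot_id, "molecule_name": t.molecule_name,
                   "retrieval_count": t.retrieval_count}
            for cid in cids:
                v, pdb = t.per_compound_best.get(cid, (float("nan"), ""))
                row[f"best_affinity_{cid}"] = v
                row[f"pdb_{cid}"] = pdb
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_json(out / "screen_report.json")
        self.top_scores_table().to_csv(out / "top_scores.tsv", sep="\t", index=False)
        self.consensus_table().to_csv(out / "consensus_targets.tsv", sep="\t",
                                      index=False)


def run_screen(
    compound_ids: Sequence[str],
    pdb_ids: Sequence[str],
    boxes: Mapping[str, "DockingBox"] | None,
    decoy_ids_by_query: Mapping[str, Sequence[str]],
    mapping: Mapping[str, str],
    backend: DockingBackend,
    filt: ScreenFilter = ScreenFilter(),
    names: Mapping[str, str] | None = None,
    exhaustiveness: int = 64,
    seed: int | None = None,
) -> ScreenReport:
    """Full pipeline: dock queries and decoys, normalize, filter, summarize.

    ``boxes`` maps pdb_id to a prepared :class:`~ivscreen.panel.DockingBox`
    (may be None for replay backends, which ignore geometry).  Raises only
    if no query job succeeds at all.
    """
    from .panel import DockingBox as _Box

    dummy = _Box(center=(0.0, 0.0, 0.0), size=(20.0, 20.0, 20.0))

    def _box(pid: str) -> "DockingBox":
        return boxes[pid] if boxes else dummy

    jobs = [DockingJob(cid, pid, _box(pid), exhaustiveness, seed)
            for cid in compound_ids for pid in pdb_ids]
    all_decoys = sorted({d for ds in decoy_ids_by_query.values() for d in ds})
    jobs += [DockingJob(did, pid, _box(pid), exhaustiveness, seed)
             for did in all_decoys for pid in pdb_ids]

    records, failures = dock_batch(jobs, backend)
    qset = set(compound_ids)
    query_records = [r for r in records if r.compound_id in qset]
    decoy_records = [r for r in records if r.compound_id not in qset]
    warnings = []
    if not query_records:
        from .errors import BatchError
        raise BatchError("no query docking job succeeded")

    hits = normalize_records(query_records, decoy_records, decoy_ids_by_query, mapping)
    passed = apply_filter(hits, filt)
    if not passed:
        warnings.append("no hit passed the retention filter; report sections empty")
    tops_aff = top_scores(passed, by="affinity", names=names)
    tops_v = top_scores(passed, by="V", names=names)
    missing = sorted(qset - {t.compound_id for t in tops_aff})
    for cid in missing:
        warnings.append(f"compound {cid}: no retained hit; omitted from top scores")
    cons = consensus_targets(passed, mapping=mapping, names=names,
                             compound_ids=list(compound_ids))
    engine_meta = records[0].engine_meta if records else {}
    return ScreenReport(
        version="1",
        filter={"e_max_kcal_mol": filt.e_max, "v_min": filt.v_min},
        engine_meta={**engine_meta, "seed": seed,
                     "exhaustiveness": exhaustiveness},
        n_query_records=len(query_records),
        n_passed=len(passed),
        hits=hits, passed=passed,
        top_by_affinity=tops_aff, top_by_V=tops_v,
        consensus=cons, warnings=warnings, failures=failures,
    )
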