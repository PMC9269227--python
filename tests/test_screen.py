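"""Normalization (V = V0/VR), retention filters, top scores and consensus."""

import collections
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivscreen.errors import NormalizationError
from ivscreen.screen import (NormalizedHit, ScreenFilter, apply_filter,
                             consensus_targets, normalize, top_scores)


def hit(cid, pdb, V0, V, uid="U1"):
    return NormalizedHit(cid, pdb, uid, V0=V0, VR=V0 / V if V else -1.0, V=V)


# ---------------------------------------------------------------------------
# Normalization

def test_identical_decoys_give_unit_v():
    VR, V = normalize(-9.0, [-9.0] * 10)
    assert (VR, V) == (-9.0, 1.0)


def test_normalization_direct_substitution():
    VR, V = normalize(-10.1, [-8.0] * 10)
    assert VR == pytest.approx(-8.0)
    assert V == pytest.approx(1.2625)


def test_normalization_errors():
    with pytest.raises(NormalizationError):
        normalize(-9.0, [])
    with pytest.raises(NormalizationError):
        normalize(-9.0, [1.0, 2.0])  # non-negative mean decoy affinity


@settings(max_examples=100, deadline=None, derandomize=True)
@given(V0=st.floats(-15, -0.1),
       decoys=st.lists(st.floats(-12, -0.5), min_size=1, max_size=10))
def test_v_equals_ratio_exactly(V0, decoys):
    VR, V = normalize(V0, decoys)
    assert V == V0 / VR


# ---------------------------------------------------------------------------
# Retention filter

@pytest.mark.parametrize("V0, V, kept", [
    (-7.4, 0.90, False),   # affinity not strictly below -7.5
    (-7.5, 0.90, False),   # boundary value: strict inequality
    (-8.0, 0.75, False),   # V not strictly above 0.75
    (-7.6, 0.80, True),
    (0.5, 2.0, False),     # non-binding score auto-fails
])
def test_filter_is_strict(V0, V, kept):
    out = apply_filter([hit("c1", "P1", V0, V)])
    assert bool(out) is kept
    if kept:
        assert out[0].passed


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hits=st.lists(
    st.tuples(st.floats(-12, -1), st.floats(0.1, 2.0)), max_size=30),
    de=st.floats(0, 3), dv=st.floats(0, 0.5))
def test_filter_monotone_under_relaxation(hits, de, dv):
    hs = [hit("c", f"P{i}", v0, v) for i, (v0, v) in enumerate(hits)]
    tight = {(h.compound_id, h.pdb_id) for h in apply_filter(hs, ScreenFilter())}
    relaxed = ScreenFilter(e_max=-7.5 + de if de < 7.5 else -0.01,
                           v_min=max(0.75 - dv, 1e-6))
    loose = {(h.compound_id, h.pdb_id) for h in apply_filter(hs, relaxed)}
    assert tight <= loose


# ---------------------------------------------------------------------------
# Top scores

def test_top_scores_by_affinity_and_by_v():
    hs = apply_filter([
        hit("c1", "AAAA", -9.0, 1.30),
        hit("c1", "BBBB", -8.0, 1.40),
        hit("c2", "CCCC", -10.0, 1.10),
    ])
    by_aff = top_scores(hs, by="affinity")
    assert [(t.compound_id, t.pdb_id, t.value) for t in by_aff] == [
        ("c1", "AAAA", -9.0), ("c2", "CCCC", -10.0)]
    by_v = top_scores(hs, by="V")
    assert by_v[0].pdb_id == "BBBB" and by_v[0].value == pytest.approx(1.40)


def test_top_scores_deterministic_pdb_tiebreak():
    hs = apply_filter([hit("c1", "ZZZZ", -9.0, 1.2),
                       hit("c1", "AAAA", -9.0, 1.2)])
    top = top_scores(hs, by="affinity")
    assert top[0].pdb_id == "AAAA" and top[0].tie


def test_compound_without_passed_hits_is_omitted():
    hs = apply_filter([hit("c1", "AAAA", -9.0, 1.3),
                       hit("c2", "BBBB", -6.0, 1.3)])  # c2 fails filter
    assert [t.compound_id for t in top_scores(hs)] == ["c1"]


def test_top_scores_rejects_unknown_criterion():
    with pytest.raises(ValueError):
        top_scores([], by="rank")


# ---------------------------------------------------------------------------
# Consensus targets

def test_consensus_matches_reported_thrombin_row():
    mapping = {"6ZUX": "P00734", "6ZV8": "P00734", "1RD3": "P00734"}
    hs = apply_filter([
        hit("cbt1", "6ZUX", -8.4, 1.3, "P00734"),
        hit("cbd", "6ZV8", -8.6, 1.3, "P00734"),
        hit("cbda", "1RD3", -8.5, 1.3, "P00734"),
    ])
    (ct,) = consensus_targets(hs, mapping=mapping)
    assert ct.uniprot_id == "P00734"
    assert ct.retrieval_count == 3
    assert ct.per_compound_best == {
        "cbt1": (-8.4, "6ZUX"), "cbd": (-8.6, "6ZV8"), "cbda": (-8.5, "1RD3")}


def test_target_missing_one_compound_is_excluded():
    hs = apply_filter([hit("c1", "AAAA", -9.0, 1.3, "U9"),
                       hit("c2", "AAAA", -9.1, 1.3, "U9")])
    assert consensus_targets(hs, compound_ids=["c1", "c2", "c3"]) == []


def test_consensus_members_all_passed_filter():
    hs = apply_filter([hit(c, f"P{i}", -8.0 - i * 0.1, 1.2, "U1")
                       for i, c in enumerate(["c1", "c2", "c3"])])
    (ct,) = consensus_targets(hs)
    assert all(v0 < -7.5 for v0, _ in ct.per_compound_best.values())


def _consensus_oracle(hits, compound_ids):
    """Exhaustive recount with plain dict/Counter bookkeeping."""
    per_uid = collections.defaultdict(list)
    for h in hits:
        per_uid[h.uniprot_id].append(h)
    rows = []
    for uid, hs in per_uid.items():
        if {h.compound_id for h in hs} >= set(compound_ids):
            best = {}
            for cid in compound_ids:
                cand = [(h.V0, h.pdb_id) for h in hs if h.compound_id == cid]
                best[cid] = min(cand)
            rows.append((uid, len(hs), best))
    rows.sort(key=lambda r: (-r[1], min(v for v, _ in r[2].values()), r[0]))
    return rows


def random_hit_table(rng, n_targets):
    compound_ids = ["c1", "c2", "c3"]
    uids = [f"U{i}" for i in range(max(1, n_targets // 2))]
    mapping = {f"P{i}": uids[rng.integers(len(uids))] for i in range(n_targets)}
    hits = []
    for cid, pdb in itertools.product(compound_ids, mapping):
        if rng.random() < 0.35:
            V0 = float(np.round(rng.uniform(-11, -7.6), 2))
            hits.append(NormalizedHit(cid, pdb, mapping[pdb], V0, -8.0,
                                      V0 / -8.0, passed=True))
    return hits, compound_ids


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_consensus_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(30):
        hits, cids = random_hit_table(rng, int(rng.integers(1, 50)))
        result = consensus_targets(hits, compound_ids=cids)
        oracle = _consensus_oracle(hits, cids)
        assert [(t.uniprot_id, t.retrieval_count, t.per_compound_best)
                for t in result] == [(u, n, b) for u, n, b in oracle]


# ---------------------------------------------------------------------------
# End-to-end replay report

def test_replay_report_is_bit_reproducible(reference_report):
    from ivscreen.refscreen import reference_screen

    assert reference_screen().to_json() == reference_report.to_json()


def test_degenerate_filter_empties_report_with_warning():
    from ivscreen.refscreen import reference_screen

    rep = reference_screen(filt=ScreenFilter(e_max=-1e9, v_min=0.75))
    assert rep.n_passed == 0
    assert rep.consensus == [] and rep.top_by_affinity == []
    assert any("no hit passed" in w for w in rep.warnings)


def test_report_tables_have_expected_layout(reference_report, tmp_path):
    reference_report.write(tmp_path)
    assert (tmp_path / "screen_report.json").exists()
    top = (tmp_path / "top_scores.tsv").read_text().splitlines()
    assert top[0].split("\t")[:3] == ["compound_id", "by", "pdb_id"]
    cons = (tmp_path / "consensus_targets.tsv").read_text().splitlines()
    assert "retrieval_count" in cons[0].split("\t")
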