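"""Synthetic-data generators: determinism, ground truth and statistics."""

import numpy as np
import pytest
from scipy import stats

from ivscreen.compounds import QUERY_COMPOUNDS, compute_properties, select_decoys
from ivscreen.docking import ReplayBackend
from ivscreen.errors import InsufficientDecoysError, ParameterError
from ivscreen.panel import read_mapping
from ivscreen.screen import ScreenFilter, run_screen
from ivscreen.synth import (SyntheticPanelSpec, ToyComplexSpec,
                            generate_affinity_table, generate_decoy_library,
                            generate_toy_complex, compound_ids, decoy_ids,
                            target_ids, write_affinity_table, write_mapping)


def _screen(spec, table, key, filt=ScreenFilter()):
    return run_screen(compound_ids(spec), target_ids(spec), None,
                      {c: decoy_ids(spec) for c in compound_ids(spec)},
                      key.mapping, ReplayBackend(table), filt=filt)


def test_affinity_table_deterministic_per_seed():
    spec = SyntheticPanelSpec(seed=5)
    t1, k1 = generate_affinity_table(spec)
    t2, k2 = generate_affinity_table(spec)
    assert t1.equals(t2) and k1 == k2
    t3, _ = generate_affinity_table(SyntheticPanelSpec(seed=6))
    assert not t1.equals(t3)


def test_spec_validation():
    with pytest.raises(ParameterError):
        SyntheticPanelSpec(n_planted=51, n_targets=50)
    with pytest.raises(ParameterError):
        SyntheticPanelSpec(base_affinity_sd=-1)
    with pytest.raises(ParameterError):
        SyntheticPanelSpec(planted_shift=1.0)


def test_planted_pairs_recovered_at_large_shift():
    """Tight noise, -3 kcal/mol shift: every planted pair passes the filter."""
    spec = SyntheticPanelSpec(base_affinity_sd=0.3, decoy_affinity_sd=0.3,
                              planted_shift=-3.0, seed=11)
    table, key = generate_affinity_table(spec)
    rep = _screen(spec, table, key)
    passed_pairs = {(h.compound_id, h.pdb_id) for h in rep.passed}
    assert key.planted_pairs <= passed_pairs


def _recovery_rate(shift, seeds, sd=0.3):
    """Fraction of planted pairs that pass and outrank all background hits."""
    ok = tot = 0
    for seed in seeds:
        spec = SyntheticPanelSpec(base_affinity_sd=sd, decoy_affinity_sd=sd,
                                  planted_shift=shift, seed=seed)
        table, key = generate_affinity_table(spec)
        rep = _screen(spec, table, key)
        planted = set(key.planted_targets)
        for cid in compound_ids(spec):
            hits = [h for h in rep.passed if h.compound_id == cid]
            bg_best = min((h.V0 for h in hits if h.pdb_id not in planted),
                          default=np.inf)
            for t in planted:
                tot += 1
                ph = [h for h in hits if h.pdb_id == t]
                ok += bool(ph and ph[0].V0 < bg_best)
    return ok / tot


def test_recovery_monotone_in_planted_shift():
    seeds = range(8)
    rates = [_recovery_rate(s, seeds) for s in (0.0, -1.0, -2.0, -3.0)]
    assert all(a <= b for a, b in zip(rates, rates[1:]))
    assert rates[-1] == 1.0


def test_null_false_positive_rate_matches_normal_tail():
    """With no planted targets the pass rate equals the analytic tail.

    A background hit passes iff V0 < -7.5 and V0/VR > 0.75, i.e.
    V0 < min(-7.5, 0.75 VR) with V0 ~ N(mu0, s0) and VR the mean of ten
    decoy draws.  The oracle integrates the normal tail over the VR
    distribution by quadrature.
    """
    spec0 = SyntheticPanelSpec(n_planted=0)
    mu0, s0 = spec0.base_affinity_mean, spec0.base_affinity_sd
    muR = spec0.decoy_affinity_mean
    sR = spec0.decoy_affinity_sd / np.sqrt(spec0.n_decoys)
    filt = ScreenFilter()

    def integrand(vr):
        bound = min(filt.e_max, filt.v_min * vr)
        return stats.norm.cdf((bound - mu0) / s0) * stats.norm.pdf(vr, muR, sR)

    from scipy.integrate import quad
    analytic, _ = quad(integrand, muR - 8 * sR, muR + 8 * sR)

    passes = trials = 0
    for seed in range(100):
        spec = SyntheticPanelSpec(n_planted=0, seed=seed)
        table, key = generate_affinity_table(spec)
        rep = _screen(spec, table, key)
        passes += rep.n_passed
        trials += spec.n_compounds * spec.n_targets
    empirical = passes / trials
    assert empirical == pytest.approx(analytic, abs=0.01)


def test_generated_artifacts_round_trip_through_pipeline_readers(tmp_path):
    spec = SyntheticPanelSpec(n_targets=10, seed=3)
    table, key = generate_affinity_table(spec)
    write_affinity_table(table, tmp_path / "aff.tsv")
    write_mapping(key.mapping, tmp_path / "map.tsv")
    backend = ReplayBackend(tmp_path / "aff.tsv")
    mapping = read_mapping(tmp_path / "map.tsv")
    assert mapping == key.mapping
    rep = run_screen(compound_ids(spec), target_ids(spec), None,
                     {c: decoy_ids(spec) for c in compound_ids(spec)},
                     mapping, backend)
    assert rep.n_query_records == spec.n_compounds * spec.n_targets


def test_toy_complex_files_are_byte_identical_per_seed(tmp_path):
    spec = ToyComplexSpec(seed=9)
    p1, s1, _ = generate_toy_complex(spec, tmp_path / "a")
    p2, s2, _ = generate_toy_complex(spec, tmp_path / "b")
    assert p1.read_bytes() == p2.read_bytes()
    assert s1.read_bytes() == s2.read_bytes()


def test_oversized_ligand_warns(tmp_path):
    with pytest.warns(UserWarning, match="does not fit"):
        generate_toy_complex(ToyComplexSpec(cavity_radius=1.2,
                                            shell_thickness=4.0), tmp_path)


def test_decoy_library_supports_ten_decoy_selection():
    q = QUERY_COMPOUNDS[1]  # CBD
    p = compute_properties(q)
    lib = generate_decoy_library(p.mw, p.hbd, p.hba, n_candidates=50, seed=0)
    assert len(lib) == 50
    ds = select_decoys(q, lib, n=10)
    assert len(ds.decoys) == 10 and ds.verify(q)


def test_small_library_raises_insufficient_decoys():
    q = QUERY_COMPOUNDS[1]
    p = compute_properties(q)
    lib = generate_decoy_library(p.mw, p.hbd, p.hba, n_candidates=5, seed=0)
    with pytest.raises(InsufficientDecoysError):
        select_decoys(q, lib, n=10)


def test_decoy_library_deterministic_per_seed():
    p = compute_properties(QUERY_COMPOUNDS[0])
    l1 = generate_decoy_library(p.mw, p.hbd, p.hba, 20, seed=4)
    l2 = generate_decoy_library(p.mw, p.hbd, p.hba, 20, seed=4)
    assert [c.structure for c in l1] == [c.structure for c in l2]
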