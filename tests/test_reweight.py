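"""Quality priors, weight initialisation and the Bayesian update, checked
against spec-level examples and an independent dense-array implementation."""

import numpy as np
import pytest

import smartmap as sm
from smartmap.bedio import AlignmentRecord
from smartmap.reweight import (
    ReweightConfig,
    alignment_quality,
    build_read_groups,
    initialize_weights,
    mean_track_weight,
    min_pair_score,
    pseudo_mapq,
    reweight_read,
    run_smartmap,
)

from _oracles import brute_force_smartmap, random_alignment_records

SMIN50 = -60.6


def test_min_pair_score_formula():
    assert min_pair_score(50) == pytest.approx(-60.6)
    assert min_pair_score(100) == pytest.approx(-120.6)


@pytest.mark.parametrize(
    "ratio,z",
    [(0.0, 42), (0.10, 42), (0.2, 42), (0.2000001, 40), (0.3, 40),
     (0.35, 24), (0.4, 24), (0.45, 23), (0.5, 23), (0.55, 8), (0.6, 8),
     (0.65, 3), (0.7, 3), (0.75, 0), (1.0, 0)],
)
def test_pseudo_mapq_bins(ratio, z):
    assert pseudo_mapq(ratio * SMIN50, SMIN50) == z


def test_pseudo_mapq_rejects_scores_below_minimum():
    with pytest.raises(ValueError):
        pseudo_mapq(-70.0, SMIN50)
    with pytest.raises(ValueError):
        pseudo_mapq(1.0, SMIN50)  # positive score


def test_alignment_quality():
    assert alignment_quality(0, scored=True) == 0.0
    assert alignment_quality(42, scored=True) == pytest.approx(1 - 10 ** -4.2)
    for z in (0, 3, 8, 23, 24, 40, 42):
        assert alignment_quality(z, scored=False) == 1.0


def _group(intervals, scores=None, read_id="r"):
    recs = []
    for j, (s, e) in enumerate(intervals):
        a_s, y_s = (scores[j] if scores else (0.0, 0.0))
        recs.append(AlignmentRecord("c", s, e, read_id, a_s, y_s))
    return build_read_groups(recs)[0]


def test_initialize_uniread_weight_is_one_and_frozen():
    cfg = ReweightConfig(scored=True, read_length=50)
    g = initialize_weights(_group([(11, 20)], [(-6, -6)]), None, cfg)
    assert g.weights.tolist() == [1.0]
    assert g.frozen


def test_initialize_equal_qualities_split_evenly():
    cfg = ReweightConfig(scored=False)
    g = initialize_weights(_group([(11, 20), (51, 60)]), None, cfg)
    assert g.weights.tolist() == [0.5, 0.5]
    assert not g.frozen


def test_initialize_discards_all_zero_quality_reads():
    # both alignments at z = 0 (ratio in (0.7, 1]) -> q = 0 -> discard
    cfg = ReweightConfig(scored=True, read_length=50)
    g = initialize_weights(
        _group([(11, 20), (51, 60)], [(-30, -20), (-25, -25)]), None, cfg
    )
    assert g is None


def test_initialize_drops_zero_weight_alignments():
    # one q=0 alignment among good ones is dropped, weights renormalised
    cfg = ReweightConfig(scored=True, read_length=50)
    g = initialize_weights(
        _group([(11, 20), (51, 60), (91, 100)], [(0, 0), (-30, -20), (0, 0)]),
        None, cfg,
    )
    assert g.k == 2
    assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert all(w > 0 for w in g.weights)


def test_mean_track_weight_examples():
    cfg = ReweightConfig(scored=False)
    track = sm.GenomeWeightTrack({"c": 100})
    # self-coverage only: one alignment with w = 0.5 over its interval
    g = initialize_weights(_group([(11, 20), (51, 60)]), track, cfg)
    assert mean_track_weight(track, g.alignments[0]) == pytest.approx(0.5)
    # add a co-extensive uniread: C = 1.5
    u = initialize_weights(_group([(11, 20)], read_id="u"), track, cfg)
    assert mean_track_weight(track, g.alignments[0]) == pytest.approx(1.5)
    # remove own weight: empty region sums to zero
    track.range_increment("c", 51, 61, -0.5)
    assert mean_track_weight(track, g.alignments[1]) == pytest.approx(0.0)


def test_toy_reweighting_example():
    """Uniread on [11,20] plus a 2-alignment read: one iteration moves the
    shared-locus alignment from 0.5 to C*q normalised = 1.5/2.0 = 0.75."""
    recs = [
        AlignmentRecord("c", 11, 20, "U"),
        AlignmentRecord("c", 11, 20, "B"),
        AlignmentRecord("c", 51, 60, "B"),
    ]
    res = run_smartmap(
        build_read_groups(recs), {"c": 100}, ReweightConfig(iterations=1, scored=False)
    )
    weights = {g.read_id: g.weights for g in res.groups}
    assert weights["U"].tolist() == [1.0]
    assert weights["B"].tolist() == pytest.approx([0.75, 0.25])


def test_rate_zero_is_exact_fixed_point():
    recs = random_alignment_records(np.random.default_rng(5), 5000, 100)
    cfg0 = ReweightConfig(iterations=0, scored=True, read_length=50)
    cfg_r0 = ReweightConfig(iterations=3, rate=0.0, scored=True, read_length=50)
    res0 = run_smartmap(build_read_groups(recs), {"c": 5000}, cfg0)
    res_r0 = run_smartmap(build_read_groups(recs), {"c": 5000}, cfg_r0)
    w0 = {g.read_id: g.weights for g in res0.groups}
    for g in res_r0.groups:
        assert np.array_equal(g.weights, w0[g.read_id])
    assert np.array_equal(res0.track.to_dense("c"), res_r0.track.to_dense("c"))


def test_symmetric_alignments_stay_equal():
    recs = [
        AlignmentRecord("c", 11, 20, "B"),
        AlignmentRecord("c", 111, 120, "B"),
    ]
    res = run_smartmap(
        build_read_groups(recs), {"c": 200}, ReweightConfig(iterations=4, scored=False)
    )
    assert res.groups[0].weights.tolist() == pytest.approx([0.5, 0.5])


def test_monotone_reallocation_toward_denser_interval():
    """With equal qualities, the alignment on the denser region strictly
    gains weight in one iteration."""
    recs = [
        AlignmentRecord("c", 11, 20, "U1"),
        AlignmentRecord("c", 11, 20, "U2"),
        AlignmentRecord("c", 11, 20, "B"),
        AlignmentRecord("c", 51, 60, "B"),
    ]
    res = run_smartmap(
        build_read_groups(recs), {"c": 100}, ReweightConfig(iterations=1, scored=False)
    )
    wb = {g.read_id: g.weights for g in res.groups}["B"]
    assert wb[0] > 0.5 > wb[1]


def test_scored_with_equal_scores_matches_unscored():
    rng = np.random.default_rng(9)
    recs = random_alignment_records(rng, 8000, 150, scored=False)
    # all pair scores equal (0): qualities all equal -> identical dynamics
    res_s = run_smartmap(
        build_read_groups(recs), {"c": 8000},
        ReweightConfig(iterations=2, scored=True, read_length=50),
    )
    res_u = run_smartmap(
        build_read_groups(recs), {"c": 8000},
        ReweightConfig(iterations=2, scored=False),
    )
    ws = {g.read_id: g.weights for g in res_s.groups}
    for g in res_u.groups:
        assert np.allclose(ws[g.read_id], g.weights, atol=1e-12)


def test_iterations_zero_returns_prior_track():
    recs = random_alignment_records(np.random.default_rng(2), 3000, 60)
    groups = build_read_groups(recs)
    cfg = ReweightConfig(iterations=0, scored=True, read_length=50)
    res = run_smartmap(groups, {"c": 3000}, cfg)
    # rebuild priors independently
    track = sm.GenomeWeightTrack({"c": 3000})
    for g in build_read_groups(recs):
        initialize_weights(g, track, cfg)
    assert np.array_equal(res.track.to_dense("c"), track.to_dense("c"))


def test_uniread_only_input_is_iteration_invariant():
    recs = [
        AlignmentRecord("c", 10 * i + 1, 10 * i + 100, f"u{i}") for i in range(20)
    ]
    res1 = run_smartmap(build_read_groups(recs), {"c": 1000},
                        ReweightConfig(iterations=0, scored=False))
    res2 = run_smartmap(build_read_groups(recs), {"c": 1000},
                        ReweightConfig(iterations=5, scored=False))
    assert np.array_equal(res1.track.to_dense("c"), res2.track.to_dense("c"))


@pytest.mark.parametrize("online", [True, False])
@pytest.mark.parametrize("rate", [1.0, 0.25])
def test_matches_brute_force_oracle(online, rate):
    """run_smartmap agrees with an independent per-bp dense implementation
    to 1e-9 per weight, in both update schedules."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        L = int(rng.integers(2_000, 20_000))
        n = int(rng.integers(50, 300))
        recs = random_alignment_records(rng, L, n)
        cfg = ReweightConfig(iterations=2, rate=rate, scored=True,
                             read_length=50, online=online)
        res = run_smartmap(build_read_groups(recs), {"c": L}, cfg)
        w_oracle, cov_oracle, _ = brute_force_smartmap(
            recs, {"c": L}, iterations=2, rate=rate, scored=True,
            s_min=cfg.s_min, online=online,
        )
        for g in res.groups:
            assert np.allclose(g.weights, w_oracle[g.read_id], atol=1e-9)
        assert np.allclose(res.track.to_dense("c"), cov_oracle["c"], atol=1e-6)


def test_per_read_and_global_conservation():
    rng = np.random.default_rng(17)
    recs = random_alignment_records(rng, 30_000, 500)
    checks = []

    def snap(it, track, groups):
        worst = max(abs(float(g.weights.sum()) - 1.0) for g in groups)
        mass = track.total_mass()
        expected = sum(
            float(np.dot(g.weights, [a.length for a in g.alignments])) for g in groups
        )
        checks.append((worst, abs(mass - expected)))

    run_smartmap(
        build_read_groups(recs), {"c": 30_000},
        ReweightConfig(iterations=3, scored=True, read_length=50),
        after_iteration=snap,
    )
    assert len(checks) == 4
    for worst, mass_err in checks:
        assert worst < 1e-9
        assert mass_err < 1e-6 * 500


def test_deterministic_given_input_order():
    rng = np.random.default_rng(23)
    recs = random_alignment_records(rng, 10_000, 200)
    cfg = ReweightConfig(iterations=2, scored=True, read_length=50)
    r1 = run_smartmap(build_read_groups(recs), {"c": 10_000}, cfg)
    r2 = run_smartmap(build_read_groups(recs), {"c": 10_000}, cfg)
    for g1, g2 in zip(r1.groups, r2.groups):
        assert np.array_equal(g1.weights, g2.weights)
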