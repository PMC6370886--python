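"""Statistical layer against closed-form and permutation oracles, plus
calibration (type-I error) and power on simulated study conditions."""

import numpy as np
import pytest
from scipy import stats as sps

from blastula import SimConfig, simulate_truth
from blastula import stats as bstats
from blastula.cellcycle import CellCycleRecord
from blastula.quantify import ExpressionRecord


def _record(tid, span):
    return ExpressionRecord(track_id=tid, onset_time_s=0.0, end_time_s=span,
                            span_s=span, onset_frame=0, end_frame=1,
                            onset_phase="S", onset_delay_s=0.0, foci_count=2)


def _cycle(tid, cycle, s):
    return CellCycleRecord(track_id=tid, cycle_length_s=cycle, s_length_s=s,
                           m_length_s=cycle - s)


def _truth_cycles(seed, **kw):
    base = dict(n_founders=8, n_generations=1, field_shape=(16, 256, 256),
                cycle_mean_min=(13.0, 17.0), cycle_sd_min=(1.0, 1.3))
    base.update(kw)
    truth = simulate_truth(SimConfig(seed=seed, **base))
    return truth


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_pearson_matches_hand_computed_closed_form():
    x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
    y = np.array([2.0, 3.5, 3.0, 8.0, 10.0])
    # textbook formula, computed independently of scipy
    r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
              / np.sqrt(np.sum((x - x.mean()) ** 2)
                        * np.sum((y - y.mean()) ** 2)))
    t_stat = r_hand * np.sqrt(3 / (1 - r_hand ** 2))
    p_hand = 2 * sps.t.sf(abs(t_stat), df=3)
    res = bstats.pearson(x, y)
    assert res.r == pytest.approx(r_hand)
    assert res.p == pytest.approx(p_hand)
    assert res.n == 5


def test_perfectly_coupled_spans_give_r_of_one():
    records = [_record(i, 100.0 + 50.0 * i) for i in range(10)]
    cycles = [_cycle(i, 600.0 + 100.0 * i, 200.0 + 100.0 * i)
              for i in range(10)]
    res = bstats.correlate_lengths(records, cycles, against="S")
    assert res.r == pytest.approx(1.0)


def test_zero_variance_is_flagged_not_crashed():
    records = [_record(i, 100.0) for i in range(5)]
    cycles = [_cycle(i, 600.0, 300.0) for i in range(5)]
    res = bstats.correlate_lengths(records, cycles, against="M")
    assert not res.valid and np.isnan(res.r)


def test_span_correlates_with_s_but_not_with_jittered_m():
    """In the generator, span ~ S-phase length while M is constant; against
    M with measurement jitter the correlation should be null in >= 90% of
    simulated replicates."""
    sig_m = 0
    n_runs = 200
    rng = np.random.default_rng(99)
    for seed in range(n_runs):
        truth = _truth_cycles(40_000 + seed)
        n = truth.nuclei[truth.nuclei.expressing]
        span = (n.end_s - n.onset_s).to_numpy()
        s_len = n.s_len_s.to_numpy()
        m_jit = n.m_len_s.to_numpy() + rng.normal(0, 20.0, len(n))
        if seed < 25:       # the positive control needs no repetition
            assert bstats.pearson(span, s_len).r > 0.5
        res_m = bstats.pearson(span, m_jit)
        if res_m.valid and res_m.p < 0.05:
            sig_m += 1
    assert sig_m / n_runs <= 0.10


# ---------------------------------------------------------------------------
# group comparisons vs oracles
# ---------------------------------------------------------------------------

def _permutation_p(a, b, stat, n_iter=4000, seed=0):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = stat(a, b)
    count = 0
    for _ in range(n_iter):
        rng.shuffle(pooled)
        if abs(stat(pooled[:len(a)], pooled[len(a):])) >= abs(obs):
            count += 1
    return (count + 1) / (n_iter + 1)


def test_rank_sum_p_matches_permutation_oracle(rng):
    a = rng.normal(0.0, 1.0, 14)
    b = rng.normal(0.8, 1.0, 12)
    res = bstats.compare_perturbation(list(a), list(b), quantity="cycle",
                                      test="mann-whitney")

    def u_stat(x, y):
        return sps.mannwhitneyu(x, y).statistic - len(x) * len(y) / 2

    p_perm = _permutation_p(a.copy(), b.copy(), u_stat)
    assert res.p == pytest.approx(p_perm, abs=0.02)


def test_t_p_matches_permutation_oracle(rng):
    a = rng.normal(0.0, 1.0, 12)
    b = rng.normal(1.0, 1.0, 12)
    res = bstats.compare_perturbation(list(a), list(b), quantity="S",
                                      test="t")

    def t_stat(x, y):
        return x.mean() - y.mean()

    p_perm = _permutation_p(a.copy(), b.copy(), t_stat, seed=3)
    assert res.p == pytest.approx(p_perm, abs=0.03)


def test_identical_groups_are_not_significant():
    a = list(np.arange(10.0))
    res = bstats.compare_perturbation(a, list(a), quantity="cycle",
                                      test="mann-whitney")
    assert res.p > 0.9


def test_anova_tukey_reports_pairwise_comparisons(rng):
    groups = {"64": rng.normal(600, 40, 15), "128": rng.normal(800, 50, 15),
              "256": rng.normal(1000, 60, 15)}
    res = bstats.anova_tukey(groups)
    assert res.p < 1e-6
    assert len(res.extra["tukey"]) == 3
    assert all(p < 0.01 for p in res.extra["tukey"].values())


def test_type_one_error_is_near_nominal_alpha():
    """Control-vs-control rank-sum comparisons of simulated S lengths reject
    at ~5%; with 200 runs the rejection count should sit inside a comfortable
    binomial band around 0.05."""
    rejections = 0
    n_runs = 200
    for seed in range(n_runs):
        a = _truth_cycles(60_000 + 2 * seed).nuclei.s_len_s
        b = _truth_cycles(60_001 + 2 * seed).nuclei.s_len_s
        res = bstats.compare_perturbation(list(a), list(b), "cycle",
                                          "mann-whitney")
        if res.p < 0.05:
            rejections += 1
    assert rejections / n_runs <= 0.105       # 0.05 + ~2.2 binomial sd


def test_chk1_elongates_s_but_not_m_in_most_replicates():
    hits = 0
    n_runs = 50
    for seed in range(n_runs):
        control = _truth_cycles(70_000 + seed)
        chk1 = _truth_cycles(80_000 + seed, perturbation="chk1")
        dt = 51.0
        rng = np.random.default_rng(seed)
        # frame-quantised measurements, like the pipeline's
        s_c = np.round(control.nuclei.s_len_s / dt) * dt
        s_t = np.round(chk1.nuclei.s_len_s / dt) * dt
        m_c = np.round(control.nuclei.m_len_s / dt + rng.normal(0, 0.5, len(control.nuclei))) * dt
        m_t = np.round(chk1.nuclei.m_len_s / dt + rng.normal(0, 0.5, len(chk1.nuclei))) * dt
        p_s = bstats.compare_perturbation(list(s_c), list(s_t), "cycle",
                                          "mann-whitney").p
        p_m = bstats.compare_perturbation(list(m_c), list(m_t), "cycle",
                                          "mann-whitney").p
        if p_s < 0.05 and p_m > 0.05:
            hits += 1
    assert hits / n_runs >= 0.90


def test_triptolide_leaves_cycle_length_unchanged():
    hits = 0
    n_runs = 50
    for seed in range(n_runs):
        control = _truth_cycles(90_000 + seed)
        trip = _truth_cycles(95_000 + seed, perturbation="triptolide")
        p = bstats.compare_perturbation(list(control.nuclei.cycle_s),
                                        list(trip.nuclei.cycle_s),
                                        "cycle", "mann-whitney").p
        if p > 0.05:
            hits += 1
    assert hits / n_runs >= 0.90


# ---------------------------------------------------------------------------
# memory
# ---------------------------------------------------------------------------

def _memory_inputs(truth):
    """Tracks/records shims built directly from truth lineage tables."""
    from blastula.tracking import NucleusTrack
    n = truth.nuclei
    tracks = []
    daughters = {}
    for _, row in n.iterrows():
        if row.mother_id >= 0:
            daughters.setdefault(int(row.mother_id), []).append(
                int(row.nucleus_id))
    for _, row in n.iterrows():
        kid = daughters.get(int(row.nucleus_id))
        tracks.append(NucleusTrack(
            track_id=int(row.nucleus_id),
            mother_track_id=None if row.mother_id < 0 else int(row.mother_id),
            daughters=tuple(kid) if kid else None, observations=[]))
    records = [_record(int(r.nucleus_id), r.end_s - r.onset_s)
               for _, r in n[n.expressing].iterrows()]
    return tracks, records


def test_memory_association_power_with_boost():
    """A +0.3 on-probability boost for daughters of expressing mothers is
    detectable in >= 80% of replicates on a 128-cell-like cohort (16
    founders followed through two cleavages, ~96 daughter pairs)."""
    hits = 0
    n_runs = 100
    for seed in range(n_runs):
        truth = _truth_cycles(30_000 + seed, n_founders=16, n_generations=2,
                              field_shape=(16, 320, 320),
                              cycle_mean_min=(10.0, 13.0, 16.0),
                              cycle_sd_min=(0.8, 1.0, 1.2),
                              p_express=0.5, memory_boost=0.3)
        tracks, records = _memory_inputs(truth)
        res = bstats.memory_analysis(tracks, records)
        if res.valid and res.p < 0.05:
            hits += 1
    assert hits / n_runs >= 0.80


def test_all_mothers_expressing_is_flagged_degenerate():
    truth = _truth_cycles(17, p_express=1.0, memory_boost=0.0)
    tracks, records = _memory_inputs(truth)
    res = bstats.memory_analysis(tracks, records)
    assert not res.valid
    assert "margin" in res.note


# ---------------------------------------------------------------------------
# ploidy
# ---------------------------------------------------------------------------

def test_tetraploid_to_diploid_modal_ratio_is_two():
    out = bstats.ploidy_comparison([2] * 40 + [1] * 3, [4] * 35 + [3] * 4,
                                   onsets_diploid=list(range(20)),
                                   onsets_tetraploid=list(range(20)))
    assert out["modal_ratio"] == pytest.approx(2.0)
    assert out["onset_comparison"].p > 0.05


def test_diploid_against_itself_gives_ratio_one():
    out = bstats.ploidy_comparison([2] * 30, [2] * 30)
    assert out["modal_ratio"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bstats.ploidy_comparison([], [2] * 3)
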