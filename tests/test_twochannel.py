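"""Two-channel stage: normalization, cutoff envelopes, probe and gene calls."""

import numpy as np
import pandas as pd
import pytest

from neurocoex.simulate import gen_two_channel
from neurocoex.twochannel import (
    IntensityCutoffs,
    call_gene_deg,
    classify_probes,
    deg_counts,
    exclusive_deg,
    fit_selfself_cutoffs,
    lowess_normalize,
)


def make_probes(a, m, reliable=True, array="a1", replicate="rep1"):
    n = len(a)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "replicate": replicate,
            "array": array,
            "A": np.asarray(a, dtype=float),
            "M": np.asarray(m, dtype=float),
            "reliable": reliable,
        }
    )


class TestLowess:
    def test_constant_m_normalizes_to_zero(self, rng):
        a = rng.uniform(6, 16, 200)
        probes = make_probes(a, np.full(200, 0.7))
        out = lowess_normalize(probes)
        assert np.allclose(out["M"], 0.0, atol=1e-8)
        assert np.allclose(out["A"], probes["A"])  # A untouched

    def test_intensity_trend_removed(self, rng):
        a = rng.uniform(6, 16, 500)
        m = 0.5 * a + rng.normal(0, 0.1, 500)
        out = lowess_normalize(make_probes(a, m))
        assert np.abs(out["M"]).mean() < np.abs(m).mean()
        slope = np.polyfit(a, out["M"], 1)[0]
        assert abs(slope) < 0.02  # residual-vs-A slope ~ 0

    def test_lowess_matches_independent_local_regression(self, rng):
        # oracle: numpy sliding local mean on sorted A reproduces the trend
        # to first order; the normalized M must decorrelate from it
        a = np.sort(rng.uniform(6, 16, 400))
        m = np.sin(a / 3.0) + rng.normal(0, 0.05, 400)
        out = lowess_normalize(make_probes(a, m), span=0.3)
        k = 80
        trend = np.convolve(m, np.ones(k) / k, mode="same")
        inner = slice(k, 400 - k)
        assert np.corrcoef(m[inner], trend[inner])[0, 1] > 0.9
        assert abs(np.corrcoef(out["M"][inner], trend[inner])[0, 1]) < 0.35

    def test_too_few_probes_refused(self):
        probes = make_probes([8, 9, 10], [0, 0, 0])
        with pytest.raises(ValueError, match="reliable probes"):
            lowess_normalize(probes)


class TestCutoffs:
    def test_zero_noise_gives_zero_envelope(self, rng):
        probes = make_probes(rng.uniform(6, 16, 500), np.zeros(500))
        cut = fit_selfself_cutoffs(probes, n_bins=5)
        assert np.allclose(cut.lower, 0) and np.allclose(cut.upper, 0)
        calls = classify_probes(make_probes([10, 10], [0.3, -0.3]), cut)
        assert list(calls["call"]) == ["up", "down"]

    def test_recovers_normal_quantiles(self, rng):
        # M ~ N(0, sigma(A)); at q=0.99 the envelope is +-2.576 sigma(A)
        n = 100_000
        a = rng.uniform(6, 16, n)
        sigma = 0.1 + 2.0 / a
        probes = make_probes(a, rng.normal(0, sigma))
        cut = fit_selfself_cutoffs(probes, n_bins=10, credibility=0.99)
        expected = 2.576 * (0.1 + 2.0 / cut.bin_mids)
        assert np.allclose(cut.upper, expected, rtol=0.08)
        assert np.allclose(cut.lower, -expected, rtol=0.08)

    def test_small_bins_merged(self, rng):
        probes = make_probes(rng.uniform(6, 16, 30), rng.normal(0, 0.1, 30))
        cut = fit_selfself_cutoffs(probes, n_bins=10, min_per_bin=20)
        assert len(cut.bin_mids) == 1

    def test_validation(self, rng):
        probes = make_probes(rng.uniform(6, 16, 100), np.zeros(100))
        with pytest.raises(ValueError):
            fit_selfself_cutoffs(probes.iloc[:0])
        with pytest.raises(ValueError):
            fit_selfself_cutoffs(probes, credibility=0.4)
        with pytest.raises(ValueError):
            IntensityCutoffs(np.array([1.0]), np.array([1.0]), np.array([0.0]), 0.99)


class TestClassify:
    def test_boundary_is_flat(self):
        cut = IntensityCutoffs(
            np.array([8.0, 12.0]), np.array([-0.5, -0.5]), np.array([0.5, 0.5]), 0.99
        )
        probes = make_probes([10, 10, 10], [0.0, 0.5, 0.51])
        calls = classify_probes(probes, cut)
        assert list(calls["call"]) == ["flat", "flat", "up"]

    def test_unreliable_passthrough(self):
        cut = IntensityCutoffs(
            np.array([8.0, 12.0]), np.array([-0.1, -0.1]), np.array([0.1, 0.1]), 0.99
        )
        probes = make_probes([10], [5.0], reliable=False)
        assert classify_probes(probes, cut)["call"].iloc[0] == "unreliable"

    def test_calibration_fresh_selfself(self):
        # fraction called non-flat on held-out null data ~ 1 - q
        selfself, _t, _tr = gen_two_channel(
            n_genes=50_000, probes_per_gene=1, n_selfself=2,
            deg_fraction=0.0, seed=13,
        )
        train = selfself[selfself["array"] == "selfself1"]
        test = selfself[selfself["array"] == "selfself2"]
        cut = fit_selfself_cutoffs(train, n_bins=20, credibility=0.99)
        calls = classify_probes(test, cut)
        rel = calls[calls["call"] != "unreliable"]
        rate = (rel["call"] != "flat").mean()
        assert rate == pytest.approx(0.01, abs=0.004)


def probe_calls(gene, replicate, calls):
    return pd.DataFrame(
        {
            "probe_id": [f"{gene}_{replicate}_{i}" for i in range(len(calls))],
            "gene_id": gene,
            "replicate": replicate,
            "array": replicate,
            "A": 10.0,
            "M": 0.0,
            "reliable": [c != "unreliable" for c in calls],
            "call": calls,
        }
    )


class TestGeneCalls:
    def test_consensus_call_at_exact_agreement_threshold(self):
        # 4 up + 1 flat in each of 3 replicates: agreement 0.8, called up
        frames = [
            probe_calls("g1", rep, ["up", "up", "up", "up", "flat"])
            for rep in ("rep1", "rep2", "rep3")
        ]
        deg = call_gene_deg(pd.concat(frames))
        assert list(deg["gene_id"]) == ["g1"]
        assert deg["direction"].iloc[0] == "up"

    def test_single_probe_excluded(self):
        frames = [probe_calls("g1", rep, ["up"]) for rep in ("rep1", "rep2")]
        assert len(call_gene_deg(pd.concat(frames))) == 0

    def test_agreement_below_threshold_excluded(self):
        frames = [
            probe_calls("g1", rep, ["up", "up", "flat"])
            for rep in ("rep1", "rep2", "rep3")
        ]
        assert len(call_gene_deg(pd.concat(frames))) == 0

    def test_reliability_majority_required(self):
        # 2 of 4 reliable is not *more than* 50%
        frames = [
            probe_calls("g1", rep, ["up", "up", "unreliable", "unreliable"])
            for rep in ("rep1", "rep2")
        ]
        assert len(call_gene_deg(pd.concat(frames))) == 0

    def test_direction_must_match_across_replicates(self):
        calls = pd.concat(
            [
                probe_calls("g1", "rep1", ["up", "up"]),
                probe_calls("g1", "rep2", ["down", "down"]),
            ]
        )
        assert len(call_gene_deg(calls)) == 0

    def test_gene_missing_from_one_replicate_excluded(self):
        calls = pd.concat(
            [
                probe_calls("g1", "rep1", ["up", "up"]),
                probe_calls("g1", "rep2", ["up", "up"]),
                probe_calls("g2", "rep1", ["up", "up"]),
            ]
        )
        with pytest.warns(UserWarning, match="subset of replicates"):
            deg = call_gene_deg(calls)
        assert list(deg["gene_id"]) == ["g1"]

    def test_raising_agreement_never_enlarges_set(self):
        selfself, test, _truth = gen_two_channel(n_genes=300, seed=21)
        cut = fit_selfself_cutoffs(selfself, n_bins=10)
        calls = classify_probes(test, cut)
        sizes = [
            len(call_gene_deg(calls, min_agreement=th))
            for th in (0.5, 0.6, 0.8, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestExclusive:
    def test_shared_gene_removed_and_empty_control_identity(self):
        case = pd.DataFrame({"gene_id": ["g1", "g2"], "direction": ["up", "down"]})
        ctrl = pd.DataFrame({"gene_id": ["g2"], "direction": ["up"]})
        out = exclusive_deg(case, ctrl)
        assert list(out["gene_id"]) == ["g1"]  # g2 shared (any direction)
        out2 = exclusive_deg(case, ctrl.iloc[:0])
        assert list(out2["gene_id"]) == ["g1", "g2"]
        assert deg_counts(out2) == {"up": 1, "down": 1, "total": 2}


def test_end_to_end_recovery_high_effect():
    """Planted DEGs with effects above 4 sigma(A) are recovered with
    sensitivity >= 0.9 and false-discovery proportion <= 0.1."""
    selfself, test, truth = gen_two_channel(
        n_genes=600, probes_per_gene=3, n_replicates=3,
        deg_fraction=0.1, effect_range=(1.8, 6.8), seed=17,
    )
    ctrl_self, ctrl_test, _ = gen_two_channel(
        n_genes=600, probes_per_gene=3, n_replicates=3, deg_fraction=0.0, seed=18
    )
    cut = fit_selfself_cutoffs(lowess_normalize(selfself))
    deg_case = call_gene_deg(classify_probes(lowess_normalize(test), cut))
    deg_ctrl = call_gene_deg(classify_probes(lowess_normalize(ctrl_test), cut))
    exclusive = exclusive_deg(deg_case, deg_ctrl)
    called = set(exclusive["gene_id"])
    true_set = set(truth.deg_genes)
    assert len(called & true_set) / len(true_set) >= 0.9
    assert len(called - true_set) / max(len(called), 1) <= 0.1
    # recovered directions match the planted ones
    directions = dict(zip(exclusive["gene_id"], exclusive["direction"]))
    correct = [directions[g] == truth.deg_genes[g] for g in called & true_set]
    assert all(correct)
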