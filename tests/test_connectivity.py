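"""Distance-rule estimation and fitting: binning, averaging, the three
families, best-fit selection, expected counts."""

import numpy as np
import pandas as pd
import pytest

from tcsim import connectivity as C
from tcsim import synth


def _grid_placements(n, side=400.0, seed=0):
    rng = np.random.default_rng(seed)
    xyz = np.zeros((n, 3))
    xyz[:, 0] = rng.uniform(-side / 2, side / 2, n)
    xyz[:, 2] = rng.uniform(-side / 2, side / 2, n)
    return xyz


def test_single_pair_in_one_bin():
    pre = np.array([[0.0, 0.0, 0.0]])
    post = np.array([[30.0, 0.0, 0.0]])
    edges = pd.DataFrame({"pre": [0], "post": [0]})
    prof = C.estimate_bin_probabilities(edges, pre, post)
    assert prof.probabilities[0] == 1.0          # bin centred at 25 um
    assert np.isnan(prof.probabilities[1:]).all()


def test_no_edges_gives_zero_bins():
    xyz = _grid_placements(50)
    prof = C.estimate_bin_probabilities(pd.DataFrame({"pre": [], "post": []}),
                                        xyz, xyz, same_population=True)
    assert (prof.probabilities[prof.present] == 0.0).all()


def test_empty_placement_rejected():
    with pytest.raises(ValueError):
        C.estimate_bin_probabilities(pd.DataFrame({"pre": [], "post": []}),
                                     np.empty((0, 3)), np.empty((0, 3)))


def test_bin_probabilities_match_binomial_oracle():
    """Estimates from synthetic instances fall within 3 binomial SE of the
    generating gaussian curve, per populated bin."""
    gt = synth.GroundTruthPathway("gaussian", (0.2, 0.0, 100.0))
    xyz = _grid_placements(200, seed=1)
    inst = synth.gen_connectome_instances(gt, xyz, xyz, n_instances=7, seed=2,
                                          same_population=True)
    profiles = [C.estimate_bin_probabilities(e, xyz, xyz, same_population=True)
                for e in inst.instances]
    mean = C.average_across_instances(profiles)
    # binomial mean per bin: the generator curve averaged over actual pairs
    d = C.xz_distances(xyz, xyz)
    off_diag = ~np.eye(len(xyz), dtype=bool)
    for k in np.nonzero(mean.present)[0]:
        in_bin = off_diag & (np.abs(d - mean.bin_centers[k]) <= 25.0)
        p_pairs = gt.probability(d[in_bin])
        p_true = p_pairs.mean()
        n = mean.pair_counts[k]  # total ordered pairs across instances
        se = np.sqrt(max((p_pairs * (1 - p_pairs)).mean(), 1e-12) / n)
        assert abs(mean.probabilities[k] - p_true) <= 3 * se + 1e-12


def test_average_identical_profiles():
    xyz = _grid_placements(40)
    gt = synth.GroundTruthPathway("exponential", (0.3, 100.0))
    inst = synth.gen_connectome_instances(gt, xyz, xyz, 1, seed=3,
                                          same_population=True)
    prof = C.estimate_bin_probabilities(inst.instances[0], xyz, xyz,
                                        same_population=True)
    mean = C.average_across_instances([prof, prof, prof])
    ok = prof.present
    assert np.allclose(mean.probabilities[ok], prof.probabilities[ok])


def test_average_of_zero_and_one():
    centers = np.array([25.0])
    a = C.DistanceBinProfile(centers, 25.0, np.array([0.0]), np.array([10]))
    b = C.DistanceBinProfile(centers, 25.0, np.array([1.0]), np.array([10]))
    assert C.average_across_instances([a, b]).probabilities[0] == 0.5


def test_average_rejects_mismatched_bins():
    a = C.DistanceBinProfile(np.array([25.0]), 25.0, np.array([0.0]), np.array([1]))
    b = C.DistanceBinProfile(np.array([75.0]), 25.0, np.array([0.0]), np.array([1]))
    with pytest.raises(ValueError):
        C.average_across_instances([a, b])


def test_seven_instance_mean_beats_single_instance():
    """Averaging across 7 instances tracks the generator better (RMS over
    bins) than single instances do, on average over seeds."""
    gt = synth.GroundTruthPathway("exponential", (0.25, 120.0))
    xyz = _grid_placements(150, seed=4)
    wins = 0
    for seed in range(5):
        inst = synth.gen_connectome_instances(gt, xyz, xyz, 7, seed=seed,
                                              same_population=True)
        profs = [C.estimate_bin_probabilities(e, xyz, xyz, same_population=True)
                 for e in inst.instances]
        mean = C.average_across_instances(profs)
        ok = mean.present
        truth = gt.probability(mean.bin_centers[ok])
        rms_mean = np.sqrt(np.mean((mean.probabilities[ok] - truth) ** 2))
        rms_single = np.mean([
            np.sqrt(np.mean((p.probabilities[ok] - truth) ** 2)) for p in profs])
        if rms_mean < rms_single:
            wins += 1
    assert wins >= 4


def _noise_free_profile(form, params):
    centers = C.DEFAULT_BIN_CENTERS
    return C.DistanceBinProfile(centers, 25.0,
                                C.evaluate_form(form, params, centers),
                                np.full(len(centers), 1000))


def test_fit_recovers_noise_free_exponential():
    prof = _noise_free_profile("exponential", (0.3, 100.0))
    fit = C.fit_probability_model(prof, "exponential")
    assert fit.params[0] == pytest.approx(0.3, rel=0.01)
    assert fit.params[1] == pytest.approx(100.0, rel=0.01)


def test_fit_all_zero_profile():
    prof = _noise_free_profile("exponential", (0.0, 100.0))
    fit = C.fit_probability_model(prof, "exponential")
    assert fit.params[0] == 0.0 and fit.sse == 0.0


def test_wrong_family_has_larger_sse():
    prof = _noise_free_profile("gaussian", (0.3, 150.0, 60.0))
    sse_exp = C.fit_probability_model(prof, "exponential").sse
    sse_gau = C.fit_probability_model(prof, "gaussian").sse
    assert sse_gau < sse_exp


@pytest.mark.parametrize("form, params", [
    ("exponential", (0.3, 100.0)),
    ("exp_linsat", (0.6, 90.0, 0.25)),
    ("gaussian", (0.3, 150.0, 60.0)),
])
def test_select_best_fit_identifies_family(form, params):
    prof = _noise_free_profile(form, params)
    assert C.select_best_fit(prof).form == form


def test_select_best_fit_zero_tie_breaks_to_exponential():
    prof = _noise_free_profile("exponential", (0.0, 100.0))
    assert C.select_best_fit(prof).form == "exponential"


def test_too_few_bins_rejected():
    prof = C.DistanceBinProfile(np.array([25.0]), 25.0, np.array([0.5]),
                                np.array([10]))
    with pytest.raises(ValueError):
        C.fit_probability_model(prof, "gaussian")


def test_fitted_probability_bounded_on_domain(rng):
    """Fits to noisy data stay within [0, 1] over [0, 400] um."""
    d_eval = np.linspace(0.0, 400.0, 401)
    for seed in range(10):
        r = np.random.default_rng(seed)
        form = ("exponential", "exp_linsat", "gaussian")[seed % 3]
        params = {"exponential": (r.uniform(0.1, 1.0), r.uniform(30, 300)),
                  "exp_linsat": (r.uniform(0.2, 2.0), r.uniform(30, 300),
                                 r.uniform(0.05, 0.9)),
                  "gaussian": (r.uniform(0.1, 1.0), r.uniform(0, 200),
                               r.uniform(20, 200))}[form]
        truth = C.evaluate_form(form, params, C.DEFAULT_BIN_CENTERS)
        noisy = np.clip(truth + r.normal(0, 0.02, truth.shape), 0, 1)
        prof = C.DistanceBinProfile(C.DEFAULT_BIN_CENTERS, 25.0, noisy,
                                    np.full(truth.shape, 500))
        fit = C.select_best_fit(prof)
        p = fit(d_eval)
        assert (p >= 0).all() and (p <= 1).all()


def test_exponential_fit_strictly_decreasing():
    prof = _noise_free_profile("exponential", (0.4, 80.0))
    fit = C.fit_probability_model(prof, "exponential")
    p = fit(np.linspace(0, 400, 100))
    assert (np.diff(p) < 0).all()


class TestExpectedCount:
    def test_trivial_bounds(self):
        xyz_pre = _grid_placements(10, seed=5)
        xyz_post = _grid_placements(10, seed=6)
        zero = C.PathwayRule("a", "b", C.FitModel("exponential", (0.0, 100.0), 0.0))
        one = C.PathwayRule("a", "b", C.FitModel("exp_linsat", (10.0, 1e4, 1.0), 0.0))
        assert C.expected_connection_count(zero, xyz_pre, xyz_post) == 0.0
        assert C.expected_connection_count(one, xyz_pre, xyz_post) == 100.0

    def test_matches_poisson_binomial_oracle(self):
        gt = synth.GroundTruthPathway("exponential", (0.3, 150.0))
        xyz = _grid_placements(60, seed=7)
        rule = C.PathwayRule("a", "a", C.FitModel("exponential", (0.3, 150.0), 0.0))
        expect = C.expected_connection_count(rule, xyz, xyz, same_population=True)
        d = C.xz_distances(xyz, xyz)
        p = gt.probability(d)
        np.fill_diagonal(p, 0.0)
        var = float((p * (1 - p)).sum())
        counts = [len(synth.gen_connectome_instances(
            gt, xyz, xyz, 1, seed=s, same_population=True).instances[0])
            for s in range(100)]
        se_mean = np.sqrt(var / 100)
        assert abs(np.mean(counts) - expect) < 3 * se_mean


def test_rules_round_trip_serialization(tmp_path):
    rules = [C.PathwayRule("A", "B", C.FitModel("gaussian", (0.2, 50.0, 80.0),
                                                1e-4), 3.5)]
    path = tmp_path / "rules.tsv"
    C.save_rules(rules, path)
    back = C.load_rules(path)
    assert back[0].pre_m_type == "A"
    assert back[0].fit.form == "gaussian"
    assert back[0].fit.params == pytest.approx((0.2, 50.0, 80.0))
    assert back[0].mean_nsyn == 3.5
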