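"""Model fitting, model selection and the residual runs test."""

import itertools
import math

import numpy as np
import pytest

from tpistab.fitting import (
    FitResult,
    ModelSpec,
    fit_model,
    residual_runs_test,
    select_model,
)
from tpistab.sedeq import HomogeneousModel, RadialScan, predict_homogeneous, reduced_buoyancy
from tpistab.synth import StudyDesign, generate_auc_dataset

MP = 24671.0


@pytest.fixture(scope="module")
def noisy_scans(design, dimer_truth):
    return generate_auc_dataset(dimer_truth, design, seed=7)


class TestFitModel:
    def test_noise_free_self_consistency(self, design, dimer_truth):
        quiet = StudyDesign(noise_sd=0.0)
        scans = generate_auc_dataset(dimer_truth, quiet, seed=0)
        res = fit_model(scans, ModelSpec("homogeneous", 2, MP), quiet.buoyancy())
        assert res.converged
        # RMS essentially zero on model-generated data
        assert res.rms < 1e-8 * np.max([s.absorbance.max() for s in scans])
        assert all(abs(b) < 1e-8 for b in res.params["baseline"])

    def test_two_parameter_fit_matches_grid_search(self, design):
        """Brute-force (Cb, eps) grid search agrees with the optimizer."""
        rotor = design.rotor(26000)
        ap = reduced_buoyancy(design.buoyancy(), rotor)
        radii = np.linspace(6.9, 7.2, 25)
        truth = HomogeneousModel(MP, n=2, bottom_conc=0.55, baseline=0.03)
        rng = np.random.default_rng(11)
        scan = RadialScan(radii, predict_homogeneous(truth, ap, radii, 7.2)
                          + rng.normal(0, 0.01, radii.size), rotor)
        res = fit_model(scan, ModelSpec("homogeneous", 2, MP), design.buoyancy())

        base = np.exp(ap * 2 * MP * (radii**2 - 7.2**2))
        best = (np.inf, None, None)
        for cb in np.linspace(0.4, 0.7, 301):
            for eps in np.linspace(-0.05, 0.1, 301):
                ssq = np.sum((scan.absorbance - cb * base - eps) ** 2)
                if ssq < best[0]:
                    best = (ssq, cb, eps)
        assert res.params["bottom_conc"][0] == pytest.approx(best[1], rel=2e-3)
        assert res.params["baseline"][0] == pytest.approx(best[2], abs=5e-4)

    def test_dimer_rms_beats_monomer_and_tetramer(self, design, noisy_scans):
        rms = {n: fit_model(noisy_scans, ModelSpec("homogeneous", n, MP),
                            design.buoyancy()).rms for n in (1, 2, 4)}
        assert rms[2] < 0.2 * rms[1]
        assert rms[2] < 0.2 * rms[4]

    def test_free_mass_recovers_monomer_mass(self, design, noisy_scans):
        res = fit_model(noisy_scans, ModelSpec("homogeneous", 2, MP, free_mass=True),
                        design.buoyancy())
        assert res.params["monomer_mass"] == pytest.approx(MP, rel=0.02)

    def test_reversible_on_dimer_data_degenerates_or_does_not_improve(
            self, design, noisy_scans):
        rev = fit_model(noisy_scans, ModelSpec("reversible", 2, MP), design.buoyancy())
        fixed = fit_model(noisy_scans, ModelSpec("homogeneous", 2, MP), design.buoyancy())
        ln_k = rev.params["ln_k"]
        monomer_share = np.mean([cb / (cb + cb**2 * math.exp(ln_k))
                                 for cb in rev.params["bottom_conc"]])
        assert ln_k < -20 or monomer_share < 0.05 or rev.rms >= 0.99 * fixed.rms

    def test_mixed_temperatures_rejected(self, design, dimer_truth):
        scans = generate_auc_dataset(dimer_truth, design, seed=0)
        warm = StudyDesign(temperature_K=298.15)
        scans2 = generate_auc_dataset(dimer_truth, warm, seed=0)
        with pytest.raises(ValueError, match="temperature"):
            fit_model([scans[0], scans2[0]], ModelSpec("homogeneous", 2, MP),
                      design.buoyancy())


class TestSelectModel:
    @pytest.mark.parametrize("rms_by_model", [
        {"1x": 5.01e-2, "2x": 7.93e-3, "4x": 6.90e-2},
        {"1x": 3.90e-2, "2x": 5.76e-3, "4x": 5.42e-2},
    ])
    def test_selects_dimer_from_reported_rms_triples(self, rms_by_model):
        cands = [FitResult.from_rms(label, rms) for label, rms in rms_by_model.items()]
        assert select_model(cands).selected.label == "2x"

    def test_single_candidate_is_selected_with_rationale(self):
        only = FitResult.from_rms("3x", 1e-2)
        choice = select_model([only])
        assert choice.selected is only
        assert "only model" in choice.rationale["3x"]

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_large_negative_ln_k_is_flagged_implausible(self):
        rev = FitResult(label="1x-2x", params={"ln_k": -42.0, "n": 2,
                                               "bottom_conc": [0.2]},
                        stderr={}, residuals=[], wssq=0.0, rms=1e-3,
                        n_points=0, n_params=3, converged=True, n_iter=1)
        fixed = FitResult.from_rms("2x", 2e-3)
        choice = select_model([rev, fixed])
        assert choice.selected.label == "2x"
        assert any("implausible" in f for f in choice.rationale["1x-2x"])

    def test_rms_tie_goes_to_fewer_parameters(self):
        a = FitResult.from_rms("2x", 1.000e-3, n_params=12)
        b = FitResult.from_rms("1x-2x", 0.999e-3, n_params=13)
        assert select_model([a, b]).selected.label == "2x"

    def test_end_to_end_selection_on_synthetic_dimer(self, design, noisy_scans):
        cands = [fit_model(noisy_scans, ModelSpec("homogeneous", n, MP),
                           design.buoyancy()) for n in (1, 2, 4)]
        assert select_model(cands).selected.label == "2x"


class TestRunsTest:
    def test_alternating_signs_are_over_dispersed(self):
        res = residual_runs_test([(-1.0) ** i for i in range(20)])
        assert res.n_runs == 20
        assert res.verdict == "over-dispersed"
        assert 0.0 < res.p_value < 0.05

    def test_two_blocks_are_systematic(self):
        res = residual_runs_test([1.0] * 10 + [-1.0] * 10)
        assert res.n_runs == 2
        assert res.p_value < 1e-4
        assert res.verdict == "systematic"

    def test_single_sign_reports_enumeration_p(self):
        res = residual_runs_test([0.5] * 12)
        assert res.n_runs == 1
        assert res.p_value == pytest.approx(2.0 ** (1 - 12))
        assert res.verdict == "systematic"

    def test_exact_enumeration_oracle_n10(self):
        """p-values match exhaustive enumeration of all sign arrangements
        with 5 positives among 10 residuals."""
        n, npos = 10, 5
        runs_counts = []
        for pos_at in itertools.combinations(range(n), npos):
            signs = [1 if i in pos_at else -1 for i in range(n)]
            runs_counts.append(1 + sum(a != b for a, b in zip(signs, signs[1:])))
        runs_counts = np.array(runs_counts)

        for observed in (2, 4, 6, 8, 10):
            p_le = np.mean(runs_counts <= observed)
            p_ge = np.mean(runs_counts >= observed)
            expected = min(1.0, 2.0 * min(p_le, p_ge))
            seq = _sequence_with_runs(n, npos, observed)
            res = residual_runs_test(seq)
            assert res.n_runs == observed
            assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            residual_runs_test([1.0])


def _sequence_with_runs(n: int, npos: int, runs: int) -> list[float]:
    """Construct a +/- sequence with the requested run count."""
    nneg = n - npos
    if runs % 2 == 0:
        k = runs // 2
        pos_blocks, neg_blocks = k, k
    else:
        pos_blocks, neg_blocks = (runs + 1) // 2, runs // 2
    pos_sizes = [npos - pos_blocks + 1] + [1] * (pos_blocks - 1)
    neg_sizes = [nneg - neg_blocks + 1] + [1] * (neg_blocks - 1)
    seq: list[float] = []
    for i in range(max(pos_blocks, neg_blocks)):
        if i < pos_blocks:
            seq += [1.0] * pos_sizes[i]
        if i < neg_blocks:
            seq += [-1.0] * neg_sizes[i]
    assert len(seq) == n
    return seq
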