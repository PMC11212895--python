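"""Fate-mapping predictions: reporter dilution and Ki67 transfer curves."""

import dataclasses

import numpy as np
import pytest

from memokin.datamodel import DilutionObservation, Subset
from memokin.models import KineticParameters, ModelTopology, close_parameters
from memokin.predictions import (
    SourceCurve,
    fit_source_dilution_curve,
    predict_label_dilution,
    predict_transfer_ki67,
)
from memokin.synthetic import default_ground_truth

TOPOLOGIES = [ModelTopology.BRANCHED, ModelTopology.LINEAR, ModelTopology.BURST]


def _dil(ts, ys):
    return [
        DilutionObservation(f"m{i}", float(t), Subset.NAIVE_CD4, float(y))
        for i, (t, y) in enumerate(zip(ts, ys))
    ]


class TestSourceCurve:
    def test_constant_data_gives_flat_curve(self):
        obs = _dil(np.linspace(0, 100, 8), np.full(8, 0.6))
        src = fit_source_dilution_curve(obs)
        assert np.allclose(src(np.array([0.0, 50.0, 100.0])), 0.6, atol=1e-4)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        ts = np.linspace(0, 150, 15)
        m0, minf, r = 0.9, 0.3, 0.03
        ys = minf + (m0 - minf) * np.exp(-r * ts) + 0.02 * rng.standard_normal(15)
        src = fit_source_dilution_curve(_dil(ts, ys))
        assert src.params[0] == pytest.approx(m0, rel=0.10)
        assert src.params[1] == pytest.approx(minf, rel=0.10)
        assert src.params[2] == pytest.approx(r, rel=0.10)

    def test_fit_is_non_increasing(self):
        rng = np.random.default_rng(6)
        ts = np.linspace(0, 120, 12)
        ys = 0.25 + 0.6 * np.exp(-0.02 * ts) + 0.02 * rng.standard_normal(12)
        src = fit_source_dilution_curve(_dil(ts, ys))
        grid = src(np.linspace(0, 120, 200))
        assert np.all(np.diff(grid) <= 1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_source_dilution_curve(_dil([0, 10], [0.9, 0.8]))


class TestLabelDilution:
    def test_closed_form_oracle(self):
        # homogeneous pool, constant source m_s: mu(t) = m_s + (mu0-m_s)e^{-ft}
        p = close_parameters(
            KineticParameters(
                epsilon=0.5, beta=0.3226, alpha_fast=0.05, alpha_slow=0.0,
                f=0.02, N_fast=1.0, N_slow=0.0,
            ),
            ModelTopology.BRANCHED,
        )
        ts = np.linspace(0, 150, 16)
        pred = predict_label_dilution(
            [p], ModelTopology.BRANCHED,
            SourceCurve(form="constant", params=(0.4,)), ts, initial_fraction=0.9,
        )
        exact = 0.4 + (0.9 - 0.4) * np.exp(-0.02 * ts)
        assert np.max(np.abs(pred.median - exact)) < 1e-8

    def test_closed_population_stays_constant(self):
        p = close_parameters(
            KineticParameters(
                epsilon=0.5, beta=0.3226, alpha_fast=0.05, alpha_slow=0.01,
                f=0.0, N_fast=0.4, N_slow=0.6, phi_fast_fraction=0.5,
            ),
            ModelTopology.BRANCHED,
        )
        pred = predict_label_dilution(
            [p], ModelTopology.BRANCHED,
            SourceCurve(form="constant", params=(0.2,)),
            np.linspace(0, 200, 9), initial_fraction=0.7,
        )
        assert np.allclose(pred.median, 0.7, atol=1e-9)

    def test_invariant_to_population_rescaling(self):
        truth = default_ground_truth(ModelTopology.BRANCHED)
        p = truth.params[next(iter(truth.params))]
        big = dataclasses.replace(p, N_fast=p.N_fast * 1e6, N_slow=p.N_slow * 1e6)
        src = SourceCurve(form="exp_plateau", params=(0.85, 0.25, 0.02))
        ts = np.linspace(0, 120, 7)
        a = predict_label_dilution([p], ModelTopology.BRANCHED, src, ts)
        b = predict_label_dilution([big], ModelTopology.BRANCHED, src, ts)
        assert np.allclose(a.median, b.median, atol=1e-9)

    def test_nonstationary_draws_rejected(self):
        p = KineticParameters(
            epsilon=0.5, beta=0.3226, alpha_fast=0.05, alpha_slow=0.0,
            f=0.02, N_fast=1.0, N_slow=0.0, delta_fast=0.4, delta_slow=0.0,
        )
        with pytest.raises(ValueError, match="non-stationary"):
            predict_label_dilution(
                [p], ModelTopology.BRANCHED,
                SourceCurve(form="constant", params=(0.4,)), [0.0, 10.0],
            )

    def test_chained_tem_band_covers_simulated_truth(self):
        # naive -> TCM -> TEM chain: the TEM band predicted from the TCM
        # trajectory should cover observations simulated from the truth
        truth = default_ground_truth(ModelTopology.BRANCHED)
        keys = list(truth.params)
        tcm_key = [k for k in keys if k[1] == Subset.TCM][0]
        tem_key = [k for k in keys if k[1] == Subset.TEM][0]
        p_tcm, p_tem = truth.params[tcm_key], truth.params[tem_key]
        src = SourceCurve(form="exp_plateau", params=(0.85, 0.25, 0.02))
        ts = np.linspace(0, 120, 9)

        covered, total = 0, 0
        rng = np.random.default_rng(12)
        for rep in range(20):
            # posterior-like parameter clouds around each truth
            def jitter(p):
                return close_parameters(
                    dataclasses.replace(
                        p,
                        alpha_fast=p.alpha_fast * np.exp(0.1 * rng.standard_normal()),
                        f=p.f * np.exp(0.1 * rng.standard_normal()),
                        delta_fast=None, delta_slow=None,
                    ),
                    ModelTopology.BRANCHED,
                )

            draws_tcm = [jitter(p_tcm) for _ in range(40)]
            draws_tem = [jitter(p_tem) for _ in range(40)]
            pred_tcm = predict_label_dilution(
                draws_tcm, ModelTopology.BRANCHED, src, ts, seed=rep
            )
            pred_tem = predict_label_dilution(
                draws_tem, ModelTopology.BRANCHED,
                pred_tcm.source_for_chaining("total"), ts, seed=rep,
            )
            # noiseless truth trajectory for TEM
            true_tcm = predict_label_dilution(
                [p_tcm], ModelTopology.BRANCHED, src, ts
            )
            true_tem = predict_label_dilution(
                [p_tem], ModelTopology.BRANCHED,
                true_tcm.source_for_chaining("total"), ts,
            )
            obs = np.clip(
                true_tem.median + 0.02 * rng.standard_normal(len(ts)), 0, 1
            )
            margin = 2 * 0.02  # observation noise around the band
            covered += int(
                np.sum((obs >= pred_tem.lo - margin) & (obs <= pred_tem.hi + margin))
            )
            total += len(ts)
        assert covered / total >= 0.90


class TestTransferKi67:
    @pytest.fixture(scope="class")
    def tem_params(self):
        truth = default_ground_truth(ModelTopology.BRANCHED)
        key = [k for k in truth.params if k[1] == Subset.TEM][0]
        return truth.params[key]

    def test_isolated_transfer_ki67_declines(self, tem_params):
        tp = predict_transfer_ki67(
            tem_params, ModelTopology.BRANCHED, "bulk", influx_on=False,
            times=[0.0, 7.0],
        )
        assert tp.ki67hi_fraction[1] < tp.ki67hi_fraction[0]

    def test_bulk_transfer_preserves_ki67(self, tem_params):
        tp = predict_transfer_ki67(
            tem_params, ModelTopology.BRANCHED, "bulk", influx_on=True,
            times=[0.0, 7.0],
        )
        assert tp.ki67hi_fraction[1] == pytest.approx(
            tp.ki67hi_fraction[0], rel=0.20
        )

    def test_no_division_pure_ki67_decay(self):
        p = close_parameters(
            KineticParameters(
                epsilon=0.5, beta=0.3226, alpha_fast=0.0, alpha_slow=0.0,
                f=0.01, N_fast=0.5, N_slow=0.5, phi_fast_fraction=0.5,
            ),
            ModelTopology.BRANCHED,
        )
        ts = np.linspace(0, 7, 8)
        tp = predict_transfer_ki67(
            p, ModelTopology.BRANCHED, "bulk", influx_on=False, times=ts
        )
        k0 = tp.ki67hi_fraction[0]
        assert np.allclose(tp.ki67hi_fraction, k0 * np.exp(-0.3226 * ts), atol=1e-8)

    @pytest.mark.parametrize("topo", TOPOLOGIES)
    def test_marked_cohort_enriched_then_converges(self, topo):
        truth = default_ground_truth(topo)
        for key in list(truth.params)[:3]:
            p = truth.params[key]
            pos = predict_transfer_ki67(p, topo, "yfp_pos", True, times=[0.0, 7.0])
            neg = predict_transfer_ki67(p, topo, "yfp_neg", True, times=[0.0, 7.0])
            bulk = predict_transfer_ki67(p, topo, "bulk", True, times=[0.0])
            # marking picks Ki67-high cells: enriched at transfer
            assert pos.ki67hi_fraction[0] > bulk.ki67hi_fraction[0]
            # decline and convergence over the following week
            gap0 = pos.ki67hi_fraction[0] - neg.ki67hi_fraction[0]
            gap7 = pos.ki67hi_fraction[1] - neg.ki67hi_fraction[1]
            assert abs(gap7) < abs(gap0)
            assert pos.ki67hi_fraction[1] < pos.ki67hi_fraction[0]

    def test_unknown_cohort(self, tem_params):
        with pytest.raises(ValueError):
            predict_transfer_ki67(tem_params, ModelTopology.BRANCHED, "zzz", True)
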