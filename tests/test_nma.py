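"""Bayesian network meta-analysis: sampler correctness and summaries."""

import math

import numpy as np
import pytest

import gdmnma as g
from gdmnma.nma import NMAModelSpec, PosteriorDraws, _gelman_rubin, league_table

from conftest import fast_spec, or_study, wmd_study


class TestFitBasics:
    def test_seed_determinism(self, toy_or_dataset):
        a = g.fit(toy_or_dataset, fast_spec(seed=42))
        b = g.fit(toy_or_dataset, fast_spec(seed=42))
        assert np.array_equal(a.d, b.d) and np.array_equal(a.tau, b.tau)
        c = g.fit(toy_or_dataset, fast_spec(seed=43))
        assert not np.array_equal(a.d, c.d)

    def test_large_study_dominates_prior(self):
        """One balanced 500/arm trial: posterior median of d sits at the
        observed log OR within MC error."""
        ds = g.OutcomeDataset("o", "OR", (
            or_study("big", 100, 500, 150, 500),
            or_study("big2", 95, 500, 155, 500),
        )).validate()
        draws = g.fit(ds, fast_spec(seed=3, samples=4000, burn_in=1000,
                                    tau_upper=1.0))
        obs = np.mean([math.log((150 * 400) / (350 * 100)),
                       math.log((155 * 405) / (345 * 95))])
        med = float(np.median(draws.contrast_draws(("insulin", "metformin"))))
        assert med == pytest.approx(obs, abs=0.1)

    def test_two_treatment_fit_tracks_dl_estimate(self):
        """On well-powered data the posterior median is close to the
        frequentist DL pooled log OR."""
        ds = g.generate_network(g.SyntheticTruth(
            seed=6, geometry={("metformin", "insulin"): 10},
            tau_true=0.1, size_range=(300, 600)))
        draws = g.fit(ds, fast_spec(seed=7, burn_in=1500, samples=5000))
        from gdmnma.drivers import analyze_edges

        dl = analyze_edges(ds)[("metformin", "insulin")].result
        med = float(np.median(draws.contrast_draws(("metformin", "insulin"))))
        assert abs(med - dl.pooled) < 0.05

    def test_disconnected_network_refused_with_components(self):
        studies = (
            or_study("a", 5, 50, 8, 50, "metformin", "insulin"),
            or_study("b", 5, 50, 8, 50, "glyburide", "acarbose"),
        )
        ds = g.OutcomeDataset("o", "OR", studies).validate()
        with pytest.raises(g.DisconnectedNetworkError, match="glyburide"):
            g.fit(ds, fast_spec(seed=1))
        # the UME model accepts the same geometry
        draws = g.fit(ds, fast_spec(seed=1, structure="ume", samples=500))
        assert draws.structure == "ume" and draws.d.shape[2] == 2

    def test_seed_required_and_chain_minimum(self, toy_or_dataset):
        with pytest.raises(g.DataValidationError, match="seed"):
            g.fit(toy_or_dataset, NMAModelSpec(likelihood="binomial-logit"))
        with pytest.raises(g.DataValidationError, match="chains"):
            g.fit(toy_or_dataset, fast_spec(seed=1, chains=1))

    def test_measure_likelihood_mismatch(self, toy_or_dataset):
        with pytest.raises(g.DataValidationError, match="measure"):
            g.fit(toy_or_dataset, fast_spec(measure="WMD", seed=1))

    def test_continuous_fit_recovers_truth(self):
        truth = g.SyntheticTruth(
            seed=9, measure="WMD",
            d_true={"metformin": -1.5, "insulin": 0.0, "glyburide": 1.0},
            baseline_dist=(12.0, 2.0), tau_true=0.2, arm_sd_typical=3.0)
        ds = g.generate_network(truth)
        draws = g.fit(ds, fast_spec("WMD", seed=10, burn_in=1500, samples=4000))
        s = g.relative_effects(draws, ("metformin", "insulin"))
        assert s.scale == "WMD"
        assert s.cri95[0] < truth.contrast("metformin", "insulin") < s.cri95[1]

    def test_multi_arm_study_accepted(self):
        sid = "three"
        s3 = g.StudyRecord(sid, (
            g.ArmRecord(sid, "metformin", 100, events=10),
            g.ArmRecord(sid, "insulin", 100, events=15),
            g.ArmRecord(sid, "glyburide", 100, events=20),
        ))
        ds = g.OutcomeDataset("o", "OR", (
            s3,
            or_study("t1", 12, 110, 18, 105),
            or_study("t2", 22, 90, 15, 95, "glyburide", "insulin"),
        )).validate()
        draws = g.fit(ds, fast_spec(seed=4, samples=1000))
        assert draws.delta.shape[2] == 4  # 2 two-arm + 2 from the 3-arm trial
        assert np.isfinite(draws.d).all()


@pytest.fixture(scope="module")
def network_draws():
    ds = g.generate_network(g.SyntheticTruth(seed=14))
    return g.fit(ds, fast_spec(seed=15, samples=2000))


class TestSummaries:
    def test_identity_pair_degenerate(self, network_draws):
        s = g.relative_effects(network_draws, ("insulin", "insulin"))
        assert s.point == 1.0 and s.cri95 == (1.0, 1.0)

    def test_reversed_pair_inverts_or_exactly(self, network_draws):
        ab = g.relative_effects(network_draws, ("metformin", "insulin"))
        ba = g.relative_effects(network_draws, ("insulin", "metformin"))
        assert ab.point * ba.point == pytest.approx(1.0, rel=1e-12)
        assert ab.cri95[0] * ba.cri95[1] == pytest.approx(1.0, rel=1e-12)

    def test_consistency_functional_identity(self, network_draws):
        """d_AC = d_AB + d_BC per draw, by construction of the model."""
        ab = network_draws.contrast_draws(("metformin", "insulin"))
        bc = network_draws.contrast_draws(("insulin", "glyburide"))
        ac = network_draws.contrast_draws(("metformin", "glyburide"))
        assert np.allclose(ac, ab + bc, atol=1e-12)

    def test_unknown_treatment_rejected(self, network_draws):
        with pytest.raises(g.DataValidationError):
            g.relative_effects(network_draws, ("metformin", "acarbose"))

    def test_league_table_row_order(self, network_draws):
        rows = league_table(network_draws)
        assert [r.pair for r in rows] == [
            ("metformin", "insulin"),
            ("metformin", "glyburide"),
            ("insulin", "glyburide"),
        ]

    def test_ume_agrees_with_consistency_on_consistent_data(self):
        ds = g.generate_network(g.SyntheticTruth(seed=21, tau_true=0.1))
        cons = g.fit(ds, fast_spec(seed=22, burn_in=1500, samples=4000))
        ume = g.fit(ds, fast_spec(seed=23, burn_in=1500, samples=4000,
                                  structure="ume"))
        for pair in [("metformin", "insulin"), ("insulin", "glyburide")]:
            c = float(np.median(cons.contrast_draws(pair)))
            u = float(np.median(ume.contrast_draws(pair)))
            assert abs(c - u) < 0.2

    def test_reference_relabeling_leaves_contrasts_invariant(self):
        """Renaming treatments so a different one is the model reference
        changes only the parameterization, not the contrasts."""
        ds = g.generate_network(g.SyntheticTruth(seed=31, tau_true=0.1))
        renamed = {"metformin": "insulin", "insulin": "metformin",
                   "glyburide": "glyburide"}
        from dataclasses import replace

        studies2 = tuple(
            replace(s, arms=tuple(replace(a, treatment=renamed[a.treatment])
                                  for a in s.arms))
            for s in ds.studies
        )
        ds2 = g.OutcomeDataset(ds.outcome, ds.measure, studies2).validate()
        a = g.fit(ds, fast_spec(seed=32, burn_in=1500, samples=4000))
        b = g.fit(ds2, fast_spec(seed=33, burn_in=1500, samples=4000))
        pa = g.relative_effects(a, ("metformin", "glyburide"))
        pb = g.relative_effects(b, ("insulin", "glyburide"))  # same arms renamed
        assert math.log(pa.point) == pytest.approx(math.log(pb.point), abs=0.06)


class TestRanks:
    def test_dominant_treatment_ranks_first(self):
        ds = g.OutcomeDataset("o", "OR", (
            or_study("s1", 5, 400, 120, 400),
            or_study("s2", 6, 400, 110, 400),
        )).validate()
        draws = g.fit(ds, fast_spec(seed=5, samples=2000, tau_upper=1.0))
        rk = g.rank_probabilities(draws, direction="lower")
        i_met = rk.treatments.index("metformin")
        assert rk.matrix[i_met, 0] > 0.999
        assert rk.best_first()[0] == "metformin"

    def test_rows_and_columns_sum_to_one(self):
        ds = g.generate_network(g.SyntheticTruth(seed=16))
        rk = g.rank_probabilities(g.fit(ds, fast_spec(seed=17, samples=1000)))
        assert np.allclose(rk.matrix.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(rk.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_direction_flag_reverses_ranking(self):
        ds = g.generate_network(g.SyntheticTruth(seed=18))
        draws = g.fit(ds, fast_spec(seed=19, samples=1000))
        lo = g.rank_probabilities(draws, direction="lower")
        hi = g.rank_probabilities(draws, direction="higher")
        assert np.allclose(lo.matrix, hi.matrix[:, ::-1], atol=1e-12)

    def test_true_ordering_recovered(self):
        """Truth metformin < insulin < glyburide on log OR: the modal
        ranking matches."""
        ds = g.generate_network(g.SyntheticTruth(seed=25))
        draws = g.fit(ds, fast_spec(seed=26, samples=2000))
        rk = g.rank_probabilities(draws, direction="lower")
        assert rk.best_first() == ["metformin", "insulin", "glyburide"]


class TestPSRF:
    def _draws(self, d):
        return PosteriorDraws(
            treatments=("metformin", "insulin"), reference="metformin",
            structure="consistency", scale="OR", d=d,
            tau=np.abs(d[:, :, 1]) + 0.1,
            mu=np.zeros((d.shape[0], d.shape[1], 1)),
            delta=np.zeros((d.shape[0], d.shape[1], 1)),
            study_ids=("s",),
        )

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(0)
        d = np.zeros((4, 2000, 2))
        d[:, :, 1] = rng.normal(0, 1, (4, 2000))
        out = g.psrf(self._draws(d))
        assert out["d[insulin]"] < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        d = np.zeros((2, 500, 2))
        d[0, :, 1] = rng.normal(0, 0.01, 500)
        d[1, :, 1] = rng.normal(5, 0.01, 500)
        assert g.psrf(self._draws(d))["d[insulin]"] > 10

    def test_single_chain_rejected(self):
        d = np.zeros((1, 100, 2))
        with pytest.raises(g.DataValidationError):
            g.psrf(self._draws(d))

    def test_matches_arviz_loosely(self):
        """Classic PSRF and arviz's rank-normalized split-Rhat agree near 1
        for well-mixed chains."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (4, 2000))
        mine = _gelman_rubin(x)
        theirs = float(az.rhat(az.convert_to_dataset(x))["x"].values)
        assert abs(mine - theirs) < 0.02
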