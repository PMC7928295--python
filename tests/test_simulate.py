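"""Synthetic-cohort generator: defaults, sampling laws, ground truth."""

import math

import numpy as np
import pytest

from robseg.cohort import write_cohort
from robseg.ice import IceConfig, classify_ice_status
from robseg.karyotype import RobTranslocation, parse_karyotype, parse_translocation
from robseg.segregation import classify_segregation
from robseg.simulate import (
    SimulationConfig,
    default_parameters,
    simulate_cohort,
    simulate_embryo,
    simulate_gamete,
)


class TestDefaults:
    def test_mode_probabilities_match_observed_gender_rates(self):
        cfg = default_parameters()
        assert cfg.mode_probs["male"][0] == pytest.approx(0.8245, abs=5e-4)
        assert cfg.mode_probs["male"][1] == pytest.approx(0.1712, abs=5e-4)
        assert cfg.mode_probs["female"][0] == pytest.approx(0.6310, abs=5e-4)
        assert cfg.mode_probs["female"][2] == pytest.approx(0.0079, abs=5e-4)
        for probs in cfg.mode_probs.values():
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_translocation_mix(self):
        cfg = default_parameters()
        assert cfg.translocation_weights["rob(13;14)(q10;q10)"] == pytest.approx(0.553)
        assert cfg.translocation_weights["rob(14;21)(q10;q10)"] == pytest.approx(0.106)
        assert len(cfg.translocation_weights) == 10
        assert sum(cfg.translocation_weights.values()) == pytest.approx(1.0)

    def test_background_rates_solve_target_proportions(self):
        cfg = default_parameters()
        lam = cfg.background_aneuploidy_rate_carrier
        assert 1 - (1 - lam) ** 20 == pytest.approx(0.2477)
        lam = cfg.background_aneuploidy_rate_control
        assert 1 - (1 - lam) ** 22 == pytest.approx(0.2025)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(mode_probs={"male": (0.5, 0.4, 0.2)})
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(mosaic_rate_carrier=1.2)

    def test_json_round_trip(self, tmp_path):
        cfg = default_parameters(seed=5)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg


class TestGamete:
    def test_degenerate_distribution_is_always_alternate(self, rob1314):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = simulate_gamete(rob1314, (1, 0, 0), rng)
            assert g.mode == "alternate" and g.deviation == (0, 0)

    def test_adjacent_products_drawn_uniformly(self, rob1314):
        rng = np.random.default_rng(1)
        n = 4000
        counts = {}
        for _ in range(n):
            g = simulate_gamete(rob1314, (0, 1, 0), rng)
            counts[g.deviation] = counts.get(g.deviation, 0) + 1
        sigma = math.sqrt(0.25 * 0.75 / n)
        for dev in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
            assert counts[dev] / n == pytest.approx(0.25, abs=3 * sigma)

    def test_fixed_seed_reproduces_sequence(self, rob1314):
        draws = lambda: [
            simulate_gamete(rob1314, (0.7, 0.25, 0.05), np.random.default_rng(42))
            for _ in range(1)
        ]
        seq1 = [simulate_gamete(rob1314, (0.7, 0.25, 0.05), np.random.default_rng(9))
                for _ in range(20)]
        seq2 = [simulate_gamete(rob1314, (0.7, 0.25, 0.05), np.random.default_rng(9))
                for _ in range(20)]
        assert seq1 == seq2


def _noise_free_config(**kw) -> SimulationConfig:
    cfg = default_parameters()
    cfg.background_aneuploidy_rate_carrier = 0.0
    cfg.background_aneuploidy_rate_control = 0.0
    cfg.mosaic_rate_carrier = 0.0
    cfg.mosaic_rate_control = 0.0
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestEmbryo:
    def _covariates(self, arm="carrier", translocation="rob(14;21)(q10;q10)"):
        return {
            "embryo_id": "E1",
            "patient_id": "P1",
            "arm": arm,
            "gender": "female",
            "age": 30,
            "translocation": translocation if arm == "carrier" else "",
        }

    def test_alternate_no_background_is_euploid(self, rob1314):
        cfg = _noise_free_config()
        rng = np.random.default_rng(0)
        g = simulate_gamete(rob1314, (1, 0, 0), rng)
        rec = simulate_embryo(g, cfg, self._covariates(translocation=str(rob1314)), rng)
        assert str(rec.karyotype) in ("46,XX", "46,XY")
        assert rec.true_mode == "alternate" and rec.true_ice == "normal"

    def test_adjacent_gamete_yields_trisomy_21(self):
        cfg = _noise_free_config()
        t = parse_translocation("rob(14;21)(q10;q10)")
        from robseg.karyotype import GameteProduct

        g = GameteProduct(t, "adjacent", (0, 1), carries_derivative=True)
        rec = simulate_embryo(g, cfg, self._covariates(), np.random.default_rng(3))
        assert str(rec.karyotype).endswith(",+21")
        assert rec.true_mode == "adjacent"

    def test_gamete_required_only_for_carriers(self, rob1314):
        cfg = _noise_free_config()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_embryo(None, cfg, self._covariates(), rng)
        g = simulate_gamete(rob1314, (1, 0, 0), rng)
        with pytest.raises(ValueError):
            simulate_embryo(g, cfg, self._covariates(arm="control"), rng)

    def test_background_rate_closed_form(self):
        """ICE-aneuploid fraction of carriers approximates 1-(1-lam)^20
        (20 eligible autosomes after excluding the translocation pair)."""
        lam = 0.014
        cfg = _noise_free_config(background_aneuploidy_rate_carrier=lam)
        t = "rob(13;14)(q10;q10)"
        rng = np.random.default_rng(11)
        n = 3000
        hits = 0
        for i in range(n):
            cov = {**self._covariates(translocation=t), "embryo_id": f"E{i}"}
            g = simulate_gamete(parse_translocation(t), (1, 0, 0), rng)
            rec = simulate_embryo(g, cfg, cov, rng)
            hits += rec.true_ice == "aneuploid"
        expected = 1 - (1 - lam) ** 20
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert hits / n == pytest.approx(expected, abs=3 * sigma)


class TestCohort:
    def test_arm_sizes_exact_and_truth_consistent(self):
        cfg = default_parameters(seed=2)
        cfg.n_carrier_embryos, cfg.n_control_embryos = 300, 200
        table = simulate_cohort(cfg)
        assert (table.df["arm"] == "carrier").sum() == 300
        assert (table.df["arm"] == "control").sum() == 200
        carriers = table.df[table.df["arm"] == "carrier"]
        for _, row in carriers.iterrows():
            call = classify_segregation(
                parse_karyotype(row["karyotype"]), parse_translocation(row["translocation"])
            )
            assert call.category == row["true_mode"]
            t = parse_translocation(row["translocation"])
            status = classify_ice_status(
                parse_karyotype(row["karyotype"]), IceConfig.for_carrier(t)
            )
            assert status.category == row["true_ice"]

    def test_empty_arm_allowed(self):
        cfg = default_parameters(seed=3)
        cfg.n_carrier_embryos, cfg.n_control_embryos = 50, 0
        table = simulate_cohort(cfg)
        assert len(table) == 50 and (table.df["arm"] == "control").sum() == 0

    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = default_parameters(seed=4)
        cfg.n_carrier_embryos, cfg.n_control_embryos = 120, 80
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(simulate_cohort(cfg), p1)
        write_cohort(simulate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.tsv.truth.tsv").read_bytes() == (
            tmp_path / "b.tsv.truth.tsv"
        ).read_bytes()

    def test_mode_proportion_recovery_within_binomial_envelope(self):
        """Classifying a simulated single-stratum cohort recovers the
        configured mode probabilities within 3 sigma."""
        cfg = _noise_free_config(seed=6)
        cfg.n_carrier_embryos, cfg.n_control_embryos = 1500, 0
        cfg.male_fraction = 1.0
        cfg.translocation_weights = {"rob(13;14)(q10;q10)": 1.0}
        p_alt = cfg.mode_probs["male"][0]
        table = simulate_cohort(cfg)
        frac = (table.df["true_mode"] == "alternate").mean()
        assert frac == pytest.approx(p_alt, abs=3 * math.sqrt(p_alt * (1 - p_alt) / 1500))

    def test_unclassifiable_rate_produces_flagged_embryos(self):
        cfg = _noise_free_config(seed=8, unclassifiable_rate=0.3)
        cfg.n_carrier_embryos, cfg.n_control_embryos = 400, 0
        table = simulate_cohort(cfg)
        n_unc = (table.df["true_mode"] == "unclassifiable").sum()
        assert 60 <= n_unc <= 180  # ~3 sigma around 120
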