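"""Statistical and determinism contracts of the cohort generator."""

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import chisquare

from ctdnatrack import synthetic_data as syn
from ctdnatrack.spectrum_summary import CATEGORIES, classify_substitution


def _dir_hashes(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
    }


class TestConfig:
    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds max"):
            syn.SimulationConfig(n_mutations_range=(45, 6))

    def test_weights_must_sum_to_one(self):
        bad = dict(syn.DEFAULT_SPECTRUM_WEIGHTS)
        bad["C>A/G>T"] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            syn.SimulationConfig(spectrum_weights=bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = syn.SimulationConfig(n_patients=4, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = syn.SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestTumorProfile:
    def test_zero_indel_fraction_all_snv(self, rng):
        cfg = syn.SimulationConfig(indel_fraction=0.0)
        mutations, _, _ = syn.simulate_tumor_profile(cfg, rng)
        assert all(m.variant.vtype == "SNV" for m in mutations)

    def test_mutation_count_within_configured_range(self, rng):
        cfg = syn.SimulationConfig()
        for _ in range(20):
            mutations, _, _ = syn.simulate_tumor_profile(cfg, rng)
            assert 6 <= len(mutations) <= 45

    def test_fixed_seed_reproducible(self):
        cfg = syn.SimulationConfig(seed=3)
        a, _, _ = syn.simulate_tumor_profile(cfg, syn.patient_rng(3, 0))
        b, _, _ = syn.simulate_tumor_profile(cfg, syn.patient_rng(3, 0))
        assert [m.variant for m in a] == [m.variant for m in b]

    def test_spectrum_recovery_at_default_weights(self, rng):
        """Empirical category frequencies of 10,000 drawn SNVs match the
        configured weights: dominant category within 3 SE, chi-square
        goodness of fit not rejected at alpha=0.01."""
        n = 10_000
        weights = syn.DEFAULT_SPECTRUM_WEIGHTS
        counts = dict.fromkeys(CATEGORIES, 0)
        for _ in range(n):
            ref, alt = syn._draw_snv_alleles(rng, weights)
            counts[classify_substitution(ref, alt)] += 1
        p0 = weights["C>A/G>T"]
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(counts["C>A/G>T"] / n - p0) <= 3 * se
        stat = chisquare(
            [counts[c] for c in CATEGORIES],
            [n * weights[c] for c in CATEGORIES],
        )
        assert stat.pvalue > 0.01


class TestTrajectory:
    def test_preop_plateau_and_postop_drop(self):
        cfg = syn.SimulationConfig()
        f, params = syn.simulate_trajectory(
            cfg, relapse=False, times=[-7, 30, 120], preop_fraction=0.01
        )
        assert f[0] == 0.01
        assert f[1] == f[2] == cfg.postop_residual_fraction

    def test_exponential_regrowth_three_months_doubling(self):
        cfg = syn.SimulationConfig(relapse_growth_fold_per_month=2.0)
        f, _ = syn.simulate_trajectory(
            cfg,
            relapse=True,
            times=[300, 390],
            preop_fraction=0.01,
            relapse_time=300.0,
        )
        assert f[0] == cfg.postop_residual_fraction
        assert f[1] == pytest.approx(8 * cfg.postop_residual_fraction)

    def test_no_relapse_non_increasing_after_surgery(self):
        cfg = syn.SimulationConfig()
        f, _ = syn.simulate_trajectory(
            cfg, relapse=False, times=[30, 120, 500, 750], preop_fraction=0.01
        )
        assert all(a >= b for a, b in zip(f, f[1:]))

    def test_capped_at_one(self):
        cfg = syn.SimulationConfig(relapse_growth_fold_per_month=4.0)
        f, _ = syn.simulate_trajectory(
            cfg, relapse=True, times=[1000], preop_fraction=0.01, relapse_time=0.0
        )
        assert f[0] == 1.0

    def test_unsorted_times_rejected(self):
        cfg = syn.SimulationConfig()
        with pytest.raises(ValueError, match="sorted"):
            syn.simulate_trajectory(cfg, False, [30, -7], preop_fraction=0.01)


def _marker(cf=1.0, shed=True, pos=1):
    from ctdnatrack.io_formats import Variant

    return syn.SimulatedMutation(
        variant=Variant("chr1", pos, "C", "A", consequence="nonsynonymous_snv"),
        clonal_fraction=cf,
        origin="tissue",
        shed=shed,
    )


class TestPlasmaSample:
    def test_zero_tumor_fraction_is_error_only(self, rng):
        """With f_t=0 the alt counts are Binomial(depth, error) draws."""
        n, depth, err = 2000, 1000, 0.001
        markers = [_marker(pos=i + 1) for i in range(n)]
        obs = syn.simulate_plasma_sample(
            markers, 0.0, (depth, depth), err, rng
        )
        mean_alt = obs["alt_count"].mean()
        se = math.sqrt(depth * err * (1 - err) / n)
        assert abs(mean_alt - depth * err) <= 3 * se

    def test_mean_simulated_vaf_recovers_expected_value(self, rng):
        """Mean VAF over 1,000 replicates at expected VAF 0.02 lands
        within 3 SE of 0.02 + error_rate."""
        n, depth, err = 1000, 1000, 0.001
        expected = 0.02 + err
        markers = [_marker(cf=1.0, pos=i + 1) for i in range(n)]
        obs = syn.simulate_plasma_sample(markers, 0.04, (depth, depth), err, rng)
        vafs = obs["alt_count"] / obs["depth"]
        se = math.sqrt(expected * (1 - expected) / depth / n)
        assert abs(vafs.mean() - expected) <= 3 * se

    def test_unshed_markers_see_error_only(self, rng):
        markers = [_marker(cf=1.0, shed=False, pos=i + 1) for i in range(500)]
        obs = syn.simulate_plasma_sample(markers, 0.5, (1000, 1000), 0.001, rng)
        assert obs["alt_count"].mean() < 3  # ~1 expected under error alone


class TestBiomarkers:
    def test_zero_sensitivity_independent_of_burden(self):
        cfg = syn.SimulationConfig(biomarker_sensitivity=0.0)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        low, _ = syn.simulate_biomarkers(0.0, cfg, rng1, responders=(False, False))
        high, _ = syn.simulate_biomarkers(0.9, cfg, rng2, responders=(False, False))
        assert low == pytest.approx(high)

    def test_responder_with_zero_noise_strictly_increasing(self):
        cfg = syn.SimulationConfig(biomarker_noise_sd=0.0)
        rng = np.random.default_rng(5)
        f = np.array([0.0, 0.01, 0.1, 0.5])
        cea, ca = syn.simulate_biomarkers(f, cfg, rng, responders=(True, True))
        assert (np.diff(cea) > 0).all() and (np.diff(ca) > 0).all()


class TestOverlapAndDeNovo:
    def test_full_overlap_no_de_novo_plasma_subset_of_tissue(self):
        cfg = syn.SimulationConfig(
            tissue_plasma_overlap=(1.0, 1.0), de_novo_plasma_rate=0.0, seed=8
        )
        sp = syn.simulate_patient(cfg, 0)
        tissue_keys = {m.variant.key for m in sp.truth.mutations if m.origin == "tissue"}
        plasma_keys = set(
            zip(sp.plasma_obs["chrom"], sp.plasma_obs["pos"],
                sp.plasma_obs["ref"], sp.plasma_obs["alt"])
        )
        decoy_keys = {v.key for v in sp.decoy_sites}
        assert plasma_keys - decoy_keys == tissue_keys
        assert all(m.shed for m in sp.truth.mutations)


class TestCohort:
    def test_file_inventory_and_relapse_count(self, cohort_dir, small_config):
        n = small_config.n_patients
        assert len(list(cohort_dir.glob("*.tissue.vcf"))) == n
        assert len(list(cohort_dir.glob("*.pbl.vcf"))) == n
        assert len(list(cohort_dir.glob("*.plasma_counts.tsv"))) == n
        truth = json.loads((cohort_dir / "ground_truth.json").read_text())
        assert sum(truth[p]["relapse"] for p in truth) == 1
        for p in truth:
            assert len(truth[p]["trajectory"]) >= 4

    def test_ground_truth_trajectory_recoverable(self, cohort_dir):
        truth = json.loads((cohort_dir / "ground_truth.json").read_text())
        for pid, t in truth.items():
            relapse_time = t["relapse_time_days"]
            for time_str, f in t["trajectory"].items():
                expected = syn.tumor_fraction_at(
                    float(time_str),
                    t["preop_fraction"],
                    5e-4,
                    relapse_time,
                    2.0,
                )
                assert f == pytest.approx(expected)

    def test_same_seed_byte_identical(self, tmp_path, small_config):
        syn.generate_cohort(small_config, tmp_path / "a")
        syn.generate_cohort(small_config, tmp_path / "b")
        hashes_a = _dir_hashes(tmp_path / "a")
        hashes_b = _dir_hashes(tmp_path / "b")
        assert hashes_a == hashes_b

    def test_adding_patients_preserves_earlier_draws(self):
        cfg6 = syn.SimulationConfig(n_patients=6, seed=4)
        cfg8 = syn.SimulationConfig(n_patients=8, seed=4)
        a = syn.simulate_patient(cfg6, 2)
        b = syn.simulate_patient(cfg8, 2)
        assert [m.variant for m in a.truth.mutations] == [
            m.variant for m in b.truth.mutations
        ]
        assert a.truth.trajectory == b.truth.trajectory
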