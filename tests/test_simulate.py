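"""Synthetic PMC generator: determinism, constraints, calibration."""

import collections

import numpy as np
import pytest

from chiasmetry import (
    ChiasmaLocalization,
    RegionBoundaries,
    SimulationConfig,
    calibrate_beta,
    classify_position,
    preset,
    preset_names,
    region_proportions,
    simulate_chiasmata,
    simulate_foci,
)
from chiasmetry.datasets import allium_chiasma_region_counts
from chiasmetry.simulate import ConfigurationError, ztp_rate_for_mean


def config(**overrides):
    base = dict(
        sample_id="S",
        n_cells=20,
        chiasma_mean=2.0,
        position_alpha=1.0,
        position_beta=1.0,
        foci_lambda_mlh1=11.05,
        foci_lambda_mus81=4.05,
        n_cells_foci_per_marker=20,
        seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"univalent_rate": 1.0},
            {"chiasma_mean": 0.0},
            {"position_alpha": -1.0},
            {"interference_min_distance": 0.6},
            {"n_cells": 0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            config(**bad)


class TestSimulateChiasmata:
    def test_same_seed_identical_output(self):
        cfg = config()
        assert simulate_chiasmata(cfg) == simulate_chiasmata(cfg)

    def test_different_seed_differs(self):
        a, _ = simulate_chiasmata(config(seed=1))
        b, _ = simulate_chiasmata(config(seed=2))
        assert a != b

    def test_obligate_crossover_without_univalents(self):
        _, bivalents = simulate_chiasmata(config(univalent_rate=0.0, n_cells=100))
        assert min(b.chiasma_count for b in bivalents) >= 1

    def test_univalent_rate_produces_univalents(self):
        _, bivalents = simulate_chiasmata(config(univalent_rate=0.3, n_cells=100))
        frac = sum(b.is_univalent_pair for b in bivalents) / len(bivalents)
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_uniform_beta_positions_split_in_thirds(self):
        cfg = config(n_cells=2000, chiasma_mean=3.0)
        chiasmata, _ = simulate_chiasmata(cfg)
        assert len(chiasmata) > 50_000
        counts = collections.Counter(classify_position(c.rel_pos) for c in chiasmata)
        for region in ("proximal", "interstitial", "distal"):
            assert counts[region] / len(chiasmata) == pytest.approx(1 / 3, abs=0.01)

    def test_bivalent_records_consistent_with_chiasmata(self):
        chiasmata, bivalents = simulate_chiasmata(config(univalent_rate=0.1))
        per_biv = collections.Counter(c.bivalent_key for c in chiasmata)
        for b in bivalents:
            assert per_biv.get(b.bivalent_key, 0) == b.chiasma_count

    def test_impossible_interference_constraint_raises(self):
        with pytest.raises(ConfigurationError, match="cannot fit"):
            simulate_chiasmata(
                config(interference_min_distance=0.4, chiasma_mean=20.0, n_cells=5)
            )

    def test_interference_respected_on_unflagged_bivalents(self):
        d = 0.1
        chiasmata, bivalents = simulate_chiasmata(
            config(interference_min_distance=d, chiasma_mean=2.5, n_cells=100)
        )
        flagged = {
            b.bivalent_key for b in bivalents if "interference_unmet" in b.subtype
        }
        arm_pos = collections.defaultdict(list)
        for c in chiasmata:
            if c.bivalent_key not in flagged:
                arm_pos[(c.bivalent_key, c.arm_id)].append(c.rel_pos)
        checked = 0
        for positions in arm_pos.values():
            if len(positions) >= 2:
                checked += 1
                assert np.min(np.diff(np.sort(positions))) >= d
        assert checked > 0


class TestSimulateFoci:
    def test_marker_means_approach_lambdas(self):
        cfg = config(n_cells_foci_per_marker=10_000)
        records = simulate_foci(cfg)
        for marker, lam in (("MLH1", 11.05), ("MUS81", 4.05)):
            counts = [r.count for r in records if r.marker == marker]
            assert np.mean(counts) == pytest.approx(lam, abs=0.1)

    def test_markers_on_distinct_slides(self):
        records = simulate_foci(config())
        slides = {r.marker: {r2.slide_id for r2 in records if r2.marker == r.marker} for r in records}
        assert slides["MLH1"] == {"slide_MLH1"}
        assert slides["MUS81"] == {"slide_MUS81"}

    def test_zero_lambda_gives_all_zero(self):
        records = simulate_foci(config(foci_lambda_mlh1=0.0, foci_lambda_mus81=0.0))
        assert all(r.count == 0 for r in records)

    def test_seeded_determinism(self):
        cfg = config()
        assert simulate_foci(cfg) == simulate_foci(cfg)


class TestCalibration:
    def test_uniform_targets_recover_uniform(self):
        alpha, beta = calibrate_beta((1 / 3, 1 / 3, 1 / 3))
        assert alpha == pytest.approx(1.0, abs=0.01)
        assert beta == pytest.approx(1.0, abs=0.01)

    def test_distal_regime_targets_recovered(self):
        targets = (18 / 1033, 207 / 1033, 808 / 1033)
        alpha, beta = calibrate_beta(targets)
        props = region_proportions(alpha, beta)
        assert props == pytest.approx(targets, abs=0.01)

    def test_reflection_symmetry(self):
        a1, b1 = calibrate_beta((0.1, 0.3, 0.6))
        a2, b2 = calibrate_beta((0.6, 0.3, 0.1))
        assert a1 == pytest.approx(b2, rel=1e-3)
        assert b1 == pytest.approx(a2, rel=1e-3)

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_beta((0.0, 0.5, 0.5))

    def test_ztp_rate_inversion(self):
        for target in (1.2, 1.95, 2.37, 3.5):
            lam = ztp_rate_for_mean(target)
            assert lam / (1 - np.exp(-lam)) == pytest.approx(target, rel=1e-9)
        with pytest.raises(ValueError):
            ztp_rate_for_mean(0.9)


class TestPresets:
    def test_unknown_preset_lists_options(self):
        with pytest.raises(KeyError, match="cepa_like"):
            preset("martian_like")

    def test_preset_proportions_match_published_triples(self, region_counts):
        for name, sample in zip(
            preset_names(),
            ("A_cepa", "A_fistulosum", "F1_diploid", "F1_triploid"),
        ):
            cfg = preset(name)
            props = region_proportions(cfg.position_alpha, cfg.position_beta)
            row = region_counts.loc[sample]
            total = row.proximal + row.interstitial + row.distal
            targets = (
                row.proximal / total,
                row.interstitial / total,
                row.distal / total,
            )
            for got, want in zip(props, targets):
                assert abs(got - want) <= 0.05

    def test_parameter_recovery_end_to_end(self):
        cfg = preset("fistulosum_like", seed=202, n_cells=200)
        chiasmata, bivalents = simulate_chiasmata(cfg)
        results = ChiasmaLocalization(chiasmata, bivalents).fit()
        (summary,) = results.summaries
        analytic = 100 * region_proportions(cfg.position_alpha, cfg.position_beta)[0]
        assert abs(summary.percent_proximal_exact - analytic) <= 3.0

    def test_opposite_regimes_strongly_separated(self):
        cepa = preset("cepa_like", seed=7, n_cells=150)
        fist = preset("fistulosum_like", seed=8, n_cells=150)
        ch_a, bv_a = simulate_chiasmata(cepa)
        ch_b, bv_b = simulate_chiasmata(fist)
        results = ChiasmaLocalization(ch_a + ch_b, bv_a + bv_b).fit()
        (pair,) = [
            r
            for r in results.pairwise
            if set(r.comparison) == {"A_cepa", "A_fistulosum"}
        ]
        assert pair.cramers_v > 0.8
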