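import numpy as np
import pytest

from mutprot.ms import match_fragments, theoretical_fragments
from mutprot.mutantdb import translate_cds
from mutprot.simulate import (
    ConfigError,
    SimulationConfig,
    generate_reference_set,
    plant_variants,
    simulate_chromatogram,
    simulate_longitudinal,
    simulate_spectrum,
)
from mutprot.variants import apply_somatic_filters


class TestConfig:
    def test_probability_bounds(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fragment_dropout=1.5)

    def test_jitter_must_stay_in_tolerance(self):
        with pytest.raises(ConfigError):
            SimulationConfig(mz_jitter_bound=0.7)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_proteins=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg
        assert SimulationConfig.from_yaml(path, seed=11).seed == 11

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("banana: 3\n")
        with pytest.raises(ConfigError):
            SimulationConfig.from_yaml(path)

    def test_stream_partitioning(self):
        cfg = SimulationConfig(seed=1)
        a1 = cfg.rng("sequences").random(5)
        a2 = cfg.rng("sequences").random(5)
        b = cfg.rng("variants").random(5)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)


class TestReferenceSet:
    def test_counts_and_invariants(self, small_config, small_reference):
        assert len(small_reference.proteins) == small_config.n_proteins
        cds_map = small_reference.cds_map()
        for acc, _gene, protein in small_reference.proteins:
            assert len(protein) >= 60
            assert set(protein) <= set("ACDEFGHIKLMNPQRSTVWY")
            cds = cds_map[acc]
            assert len(cds) % 3 == 0
            translated, stop = translate_cds(cds)
            assert stop and translated == protein

    def test_determinism(self, small_config):
        a = generate_reference_set(small_config)
        b = generate_reference_set(small_config)
        assert a == b

    def test_seed_changes_output(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert generate_reference_set(other) != generate_reference_set(small_config)


class TestPlantVariants:
    def test_determinism(self, small_config, small_reference):
        v1, t1 = plant_variants(small_reference, small_config)
        v2, t2 = plant_variants(small_reference, small_config)
        assert v1 == v2
        assert [p.variant for p in t1.planted] == [p.variant for p in t2.planted]

    def test_counts_and_flavors(self, small_config, small_reference):
        variants, truth = plant_variants(small_reference, small_config)
        flavors = [p.flavor for p in truth.planted]
        n_somatic = small_config.n_missense + small_config.n_frameshift
        assert flavors.count("somatic") == n_somatic
        for clause in ("neg_i", "neg_ii", "neg_iii", "neg_iv"):
            assert flavors.count(clause) == small_config.n_negatives_per_clause

    def test_normal_alt_negative_labeled_non_somatic(self, small_config,
                                                     small_reference):
        _, truth = plant_variants(small_reference, small_config)
        for p in truth.planted:
            if p.variant.normal_alt_reads >= 3:
                assert not p.is_somatic

    def test_each_negative_fails_its_clause(self, small_config, small_reference):
        variants, truth = plant_variants(small_reference, small_config)
        results = {r.variant.key: r for r in apply_somatic_filters(variants)}
        clause_of = {"neg_i": "i", "neg_ii": "ii", "neg_iii": "iii", "neg_iv": "iv"}
        for p in truth.planted:
            r = results[p.variant.key]
            if p.is_somatic:
                assert r.passed
            else:
                assert clause_of[p.flavor] in r.failed_clauses

    def test_filter_recovers_planted_truth_exactly(self, small_config,
                                                   small_reference):
        variants, truth = plant_variants(small_reference, small_config)
        passed = {r.variant.key for r in apply_somatic_filters(variants) if r.passed}
        assert passed == truth.somatic_keys

    def test_binomial_mean_three_se(self):
        cfg = SimulationConfig(seed=77, n_proteins=60, n_missense=1000,
                               n_frameshift=0, n_negatives_per_clause=0,
                               vaf_min=0.5, vaf_max=0.5,
                               min_protein_len=150, max_protein_len=400)
        ref = generate_reference_set(cfg)
        variants, _ = plant_variants(ref, cfg)
        assert len(variants) == 1000
        ratios = np.array([v.tumor_alt_reads / v.tumor_total_reads
                           for v in variants])
        se = np.sqrt(0.25 / np.mean([v.tumor_total_reads for v in variants]))
        assert abs(ratios.mean() - 0.5) <= 3 * se / np.sqrt(len(ratios))

    def test_too_many_variants(self, small_config, small_reference):
        import dataclasses

        greedy = dataclasses.replace(small_config, n_missense=100000)
        from mutprot.simulate import GenerationError

        with pytest.raises(GenerationError):
            plant_variants(small_reference, greedy)


class TestSimulateSpectrum:
    SEQ = "NISSDLDGHPVPK"

    def noiseless_cfg(self):
        return SimulationConfig(seed=0, fragment_dropout=0.0, n_noise_peaks=0,
                                mz_jitter_sd=0.0, intensity_cv=0.0)

    def test_noiseless_peaks_equal_theoretical_set(self):
        spec = simulate_spectrum(self.SEQ, 2, self.noiseless_cfg())
        theo = sorted(t.mz for t in theoretical_fragments(self.SEQ))
        np.testing.assert_allclose(spec.mz, theo, atol=1e-9)

    def test_full_dropout_leaves_noise_only(self):
        cfg = SimulationConfig(seed=1, fragment_dropout=1.0, n_noise_peaks=7)
        spec = simulate_spectrum(self.SEQ, 2, cfg)
        assert len(spec) == 7

    def test_noiseless_self_match_count(self):
        spec = simulate_spectrum(self.SEQ, 2, self.noiseless_cfg())
        matches = match_fragments(theoretical_fragments(self.SEQ), spec)
        assert len(matches) == 2 * (len(self.SEQ) - 1)

    def test_charge_bounds(self):
        with pytest.raises(ValueError):
            simulate_spectrum(self.SEQ, 6, self.noiseless_cfg())

    def test_determinism(self):
        cfg = SimulationConfig(seed=12)
        a = simulate_spectrum(self.SEQ, 2, cfg)
        b = simulate_spectrum(self.SEQ, 2, cfg)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestSimulateChromatogram:
    def test_equal_amounts_unit_ratio(self):
        from mutprot.prm import quantify_pair

        cfg = SimulationConfig(seed=0)
        light, heavy = simulate_chromatogram(10.0, 10.0, cfg)
        amount, ok = quantify_pair(light, heavy, 10.0)
        assert ok and amount == pytest.approx(10.0, rel=1e-6)

    def test_zero_analyte_baseline_only(self):
        cfg = SimulationConfig(seed=0)
        light, _heavy = simulate_chromatogram(0.0, 10.0, cfg)
        assert np.all(light.intensity == 0.0)

    def test_half_ratio_within_integration_tolerance(self):
        from mutprot.prm import detect_peak

        cfg = SimulationConfig(seed=0)
        light, heavy = simulate_chromatogram(5.0, 10.0, cfg)
        window = (float(light.rt[0]), float(light.rt[-1]))
        ratio = (detect_peak(light, window).area
                 / detect_peak(heavy, window).area)
        assert ratio == pytest.approx(0.5, rel=1e-3)

    def test_coelution(self):
        cfg = SimulationConfig(seed=0)
        light, heavy = simulate_chromatogram(5.0, 10.0, cfg)
        il, ih = int(np.argmax(light.intensity)), int(np.argmax(heavy.intensity))
        assert light.rt[il] == heavy.rt[ih]

    def test_bad_interval(self):
        with pytest.raises(ConfigError):
            SimulationConfig(sampling_interval=0.0)


class TestSimulateLongitudinal:
    def test_null_fold_change(self):
        cfg = SimulationConfig(seed=0, transition_cv=0.0)
        _traces, truth = simulate_longitudinal(20.0, 1.0, ["pre", "p3", "p6"], cfg)
        assert set(truth.values()) == {20.0}

    def test_zero_fold_baseline_only(self):
        cfg = SimulationConfig(seed=0, transition_cv=0.0)
        traces, truth = simulate_longitudinal(20.0, 0.0, ["pre", "p3"], cfg)
        assert truth["p3"] == 0.0
        for (tp, _tr), (light, _heavy) in traces.items():
            if tp == "p3":
                assert np.all(light.intensity == 0.0)

    def test_empty_timepoints(self):
        with pytest.raises(ValueError):
            simulate_longitudinal(20.0, 0.05, [], SimulationConfig(seed=0))

    def test_power_fold_005(self):
        # Monte-Carlo power of the paired pre/post test at fold change 0.05
        from mutprot.prm import paired_pre_post_test, quantify_pair

        hits = 0
        n_seeds = 40  # full 200-seed sweep lives in the acceptance suite
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, transition_cv=0.2, n_transitions=3)
            rng = cfg.rng("chromatograms")
            pre, post = {}, {}
            for analyte in ("A", "B", "C"):
                traces, _ = simulate_longitudinal(
                    20.0, 0.05, ["pre", "p3"], cfg, rng, analyte_id=analyte)
                per = {}
                for (tp, _tr), (light, heavy) in traces.items():
                    amount, _ = quantify_pair(light, heavy, cfg.spike_amount)
                    per.setdefault(tp, []).append(amount)
                pre[analyte] = float(np.mean(per["pre"]))
                post[analyte] = float(np.mean(per["p3"]))
            _t, p, degenerate = paired_pre_post_test(pre, post)
            hits += (not degenerate) and p < 0.05
        assert hits >= int(0.95 * n_seeds)
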