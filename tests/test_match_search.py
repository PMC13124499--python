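import numpy as np
import pytest

from mutprot.ms import (
    PSM,
    IsotopeLabel,
    Spectrum,
    estimate_qvalues,
    fragment_mz,
    heavy_mass_shift,
    match_fragments,
    peptide_mass,
    precursor_mz,
    score_psm,
    search,
    shift_y_ions,
    site_determining_ions,
    site_supported,
    spectral_similarity,
    theoretical_fragments,
)
from mutprot.ms.digest import Peptide
from mutprot.mutantdb import assemble_personalized_db, build_missense_entry
from mutprot.simulate import SimulationConfig, simulate_spectrum


def noiseless(seq, charge=2):
    cfg = SimulationConfig(seed=0, fragment_dropout=0.0, n_noise_peaks=0,
                           mz_jitter_sd=0.0, intensity_cv=0.0)
    return simulate_spectrum(seq, charge, cfg)


def make_psm(seq, mut_offset, matched_keys, is_decoy=False):
    pep = Peptide(sequence=seq, start_offset=1, missed_cleavages=0,
                  is_mutant=True, mut_offset_in_peptide=mut_offset)
    matched = tuple(
        type("M", (), {"series": s, "index": i})() for s, i in matched_keys
    )
    return PSM(spectrum_id="s", peptide=pep, score=1.0, matched=matched,
               is_decoy=is_decoy)


class TestMatchFragments:
    def test_self_spectrum_all_matched(self):
        seq = "NISSDLDGHPVPK"
        spec = noiseless(seq)
        matches = match_fragments(theoretical_fragments(seq), spec)
        assert len(matches) == 2 * (len(seq) - 1)

    def test_empty_spectrum(self):
        spec = Spectrum("e", 500.0, 2, np.array([]), np.array([]))
        assert match_fragments(theoretical_fragments("SAMPLER"), spec) == []

    def test_jitter_within_tolerance_all_matched(self):
        seq = "GDEEGVPAVVIHMSGLR"
        cfg = SimulationConfig(seed=5, fragment_dropout=0.0, n_noise_peaks=0,
                               mz_jitter_sd=0.1, mz_jitter_bound=0.3,
                               intensity_cv=0.0)
        spec = simulate_spectrum(seq, 2, cfg)
        matches = match_fragments(theoretical_fragments(seq), spec)
        assert len(matches) == 2 * (len(seq) - 1)
        assert all(abs(m.error_da) <= 0.6 for m in matches)

    def test_one_da_shift_matches_nothing(self):
        # poly-G ladder: all inter-ion gaps >= 18 Da, so a 1.0 Da shift
        # leaves nothing inside the +/-0.6 Da window
        seq = "GGGGGGGG"
        spec = noiseless(seq)
        shifted = Spectrum("s", spec.precursor_mz, 2,
                           spec.mz + 1.0, spec.intensity)
        assert match_fragments(theoretical_fragments(seq), shifted, 0.6) == []

    def test_each_peak_used_once(self):
        seq = "SAMPLER"
        spec = noiseless(seq)
        matches = match_fragments(theoretical_fragments(seq, (1, 2)), spec)
        observed = [m.observed_mz for m in matches]
        assert len(observed) == len(set(observed))


class TestScorePsm:
    def test_perfect_score_closed_form(self):
        seq = "NISSDLDGHPVPK"
        score, matched = score_psm(seq, noiseless(seq))
        n = len(seq)
        assert score == pytest.approx(2 * (n - 1) + 1, abs=1e-9)
        assert len(matched) == 2 * (n - 1)

    def test_empty_spectrum_scores_zero(self):
        spec = Spectrum("e", 500.0, 2, np.array([]), np.array([]))
        score, matched = score_psm("SAMPLER", spec)
        assert score == 0.0 and matched == []

    def test_half_fragments_removed(self):
        seq = "SAMPLEPPTIDEK"
        spec = noiseless(seq)
        n = len(seq)
        keep = np.arange(len(spec.mz)) % 2 == 0
        half = Spectrum("h", spec.precursor_mz, 2, spec.mz[keep],
                        spec.intensity[keep])
        _score, matched = score_psm(seq, half)
        assert len(matched) == (n - 1)


class TestSiteDeterminingIons:
    def test_mutation_at_first_residue(self):
        n = 10
        ions = site_determining_ions(n, 1)
        assert ions == {("b", i) for i in range(1, n)} | set()
        # y_n is not an enumerable fragment (index max n-1): all b only

    def test_mutation_at_last_residue(self):
        n = 10
        ions = site_determining_ions(n, n)
        assert ions == {("y", j) for j in range(1, n)}

    def test_lcp1_peptide_y6_is_site_determining(self):
        # 17-mer with substitution at offset 12: b12..b16 and y6..y16
        ions = site_determining_ions(17, 12)
        assert ions == ({("b", i) for i in range(12, 17)}
                        | {("y", j) for j in range(6, 17)})
        assert ("y", 6) in ions

    def test_site_supported(self):
        psm_yes = make_psm("GDEEGVPAVVIHMSGLR", 12, [("y", 6)])
        psm_no = make_psm("GDEEGVPAVVIHMSGLR", 12, [("b", 3), ("y", 2)])
        assert site_supported(psm_yes)
        assert not site_supported(psm_no)

    def test_strict_mode_requires_full_ladder(self):
        seq = "SAMPLER"
        n = len(seq)
        full = [("b", i) for i in range(1, n)]
        psm_full = make_psm(seq, 3, full)
        psm_gap = make_psm(seq, 3, full[:-2] + [("y", 1)])
        assert site_supported(psm_full, strict=True)
        assert not site_supported(psm_gap, strict=True)

    def test_non_mutant_undefined(self):
        pep = Peptide(sequence="SAMPLER", start_offset=1, missed_cleavages=0)
        psm = PSM("s", pep, 1.0, (), False)
        with pytest.raises(ValueError):
            site_supported(psm)


class TestSpectralSimilarity:
    def test_identical_spectra(self):
        spec = noiseless("SAMPLER")
        sim, ok = spectral_similarity(spec, spec)
        assert ok and sim == pytest.approx(1.0)

    def test_disjoint_spectra(self):
        a = Spectrum("a", 500, 2, np.array([100.0, 200.0]), np.array([1.0, 1.0]))
        b = Spectrum("b", 500, 2, np.array([700.0, 800.0]), np.array([1.0, 1.0]))
        sim, ok = spectral_similarity(a, b)
        assert ok and sim == 0.0

    def test_empty_flagged(self):
        a = Spectrum("a", 500, 2, np.array([]), np.array([]))
        b = noiseless("SAMPLER")
        assert spectral_similarity(a, b) == (0.0, False)

    def test_symmetry(self):
        cfg = SimulationConfig(seed=8)
        a = simulate_spectrum("GDEEGVPAVVIHMSGLR", 2, cfg, cfg.rng("spectra"))
        b = noiseless("GDEEGVPAVVIHMSGLR")
        assert spectral_similarity(a, b)[0] == pytest.approx(
            spectral_similarity(b, a)[0], abs=1e-12)

    def test_heavy_shift_invariance(self):
        seq = "GDEEGVPAVVIHMSGLR"
        delta = heavy_mass_shift(IsotopeLabel("R", 6, 4))
        light = noiseless(seq)
        # synthetic heavy spectrum: y-ions moved by the label delta
        heavy_mz = []
        y_set = {round(t.mz, 4) for t in theoretical_fragments(seq)
                 if t.series == "y"}
        for mz in light.mz:
            heavy_mz.append(mz + delta if round(mz, 4) in y_set else mz)
        heavy = Spectrum("heavy", light.precursor_mz + delta / 2, 2,
                         np.array(heavy_mz), light.intensity.copy())
        back = shift_y_ions(heavy, seq, -delta, current_shift=delta)
        sim_back, _ = spectral_similarity(light, back)
        sim_light, _ = spectral_similarity(light, light)
        assert sim_back == pytest.approx(sim_light, abs=1e-9)


class TestCoverageMatrix:
    def test_text_rendering(self):
        from mutprot.ms import coverage_matrix, score_psm

        seq = "SAMPLEK"
        spec = noiseless(seq)
        score, matched = score_psm(seq, spec)
        psm = PSM("s", Peptide(seq, 1, 0), score, tuple(matched), False)
        text = coverage_matrix(psm)
        lines = text.splitlines()
        assert lines[0].strip() == seq
        # full ladder: every bond covered in both series
        assert lines[1] == "b " + "b" * (len(seq) - 1) + "-"
        assert lines[2] == "y " + "y" * (len(seq) - 1) + "-"


class TestQValues:
    def test_separated_targets_q_zero(self):
        psms = [make_psm("SAMPLER", 1, [], is_decoy=(i >= 5)) for i in range(10)]
        psms = [PSM(p.spectrum_id, p.peptide, score=100 - i, matched=(),
                    is_decoy=(i >= 5)) for i, p in enumerate(psms)]
        out = estimate_qvalues(psms)
        assert all(p.q_value == 0.0 for p in out if not p.is_decoy)

    def test_alternating_equal_scores_q_near_one(self):
        psms = []
        for i in range(10):
            psms.append(PSM(f"s{i}", Peptide("SAMPLER", 1, 0), score=5.0,
                            matched=(), is_decoy=(i % 2 == 1)))
        out = estimate_qvalues(psms)
        assert all(p.q_value == pytest.approx(1.0) for p in out)

    def test_twelve_psm_hand_oracle(self):
        # hand-enumerated: cumulative decoy/target ratios then running min
        rows = [  # (score, is_decoy, expected_q)
            (10.0, False, 0.0),
            (9.0, False, 0.0),
            (8.0, True, 0.25),
            (7.0, False, 0.25),
            (6.0, False, 0.25),
            (5.0, True, 0.4),
            (4.0, False, 0.4),
            (3.0, True, 0.5),
            (2.0, False, 0.5),
            (1.0, True, 4 / 7),
            (0.5, False, 4 / 7),
            (0.2, True, 5 / 7),
        ]
        psms = [PSM(f"s{i}", Peptide("SAMPLER", 1, 0), score=s, matched=(),
                    is_decoy=d) for i, (s, d, _q) in enumerate(rows)]
        out = estimate_qvalues(psms)
        for psm, (_s, _d, expected) in zip(out, rows):
            assert psm.q_value == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_descending_score(self):
        rng = np.random.default_rng(2)
        psms = [PSM(f"s{i}", Peptide("SAMPLER", 1, 0),
                    score=float(rng.uniform(0, 50)), matched=(),
                    is_decoy=bool(rng.random() < 0.5)) for i in range(200)]
        out = estimate_qvalues(psms)
        ordered = sorted(out, key=lambda p: -p.score)
        qs = [p.q_value for p in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_empty(self):
        assert estimate_qvalues([]) == []


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(0)
    aas = list("ADEFGHILNPQSTVWY")  # no K/R/C/M: cleavage controlled below
    proteins = []
    for i in range(20):
        core = "".join(rng.choice(aas, size=12))
        proteins.append((f"P{i}", f"M{core}K{core[::-1]}R"))
    return assemble_personalized_db(proteins, [])


class TestSearch:

    def test_noiseless_planted_recovery(self, db):
        from mutprot.ms.digest import digest

        peptides = []
        for rec in db.targets[:20]:
            peptides.extend(p.sequence for p in digest(rec.sequence, 0))
        peptides = sorted(set(peptides))[:20]
        spectra = [noiseless(seq) for seq in peptides]
        psms, unidentified = search(spectra, db)
        assert not unidentified
        assert len(psms) == len(spectra)
        by_id = {p.spectrum_id: p for p in psms}
        for seq in peptides:
            assert by_id[f"sim:{seq}/2"].peptide.sequence == seq
            assert not by_id[f"sim:{seq}/2"].is_decoy

    def test_50ppm_off_unidentified(self, db):
        from mutprot.ms.digest import digest

        seq = next(p.sequence for p in digest(db.targets[0].sequence, 0))
        spec = noiseless(seq)
        off = Spectrum("off", spec.precursor_mz * (1 + 50e-6), 2,
                       spec.mz, spec.intensity)
        _psms, unidentified = search([off], db)
        assert unidentified == ["off"]

    def test_unsupported_charge_skipped(self, db):
        spec = noiseless("SAMPLER", charge=1)
        _psms, unidentified = search([spec], db, charges=(2, 3, 4, 5))
        assert unidentified == [spec.spectrum_id]

    def test_oxidized_met_identified(self):
        from mutprot.ms.masses import OXIDATION

        db = assemble_personalized_db([("PM", "MAAGMTIDELVNKAAGGGTIDELVNR")], [])
        mods = ((5, OXIDATION),)
        spec = simulate_spectrum(
            "MAAGMTIDELVNK", 2,
            SimulationConfig(seed=0, fragment_dropout=0.0, n_noise_peaks=0,
                             mz_jitter_sd=0.0, intensity_cv=0.0),
            spectrum_id="ox", variable_mods=mods)
        psms, unidentified = search([spec], db)
        assert not unidentified
        assert psms[0].peptide.sequence == "MAAGMTIDELVNK"
        assert psms[0].peptide.modifications == mods
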