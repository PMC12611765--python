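"""Fragment prediction, spectrum matching, evidence and KMD-RT filters."""

import numpy as np
import pytest

from epilipid.chem import FattyAcyl, ModificationSet, adduct_mz, parse_lipid_name, species_formula
from epilipid.identification import (
    CentroidSpectrum,
    MatchSettings,
    UnmodifiedSpecies,
    collapse_isomers,
    kmd_rt_filter,
    match_spectrum,
    oxfa_evidence_filter,
    predict_fragments,
)
from epilipid.synthetic import simulate_kmd_rt_series


def oxygen_accounting_oracle(chain_mods: ModificationSet, waters_lost: int) -> bool:
    """Brute-force oracle: added oxygens minus one per water loss must
    leave at least one modification oxygen on the fragment."""
    return chain_mods.added_oxygens - waters_lost >= 1


def _spectrum_for(species, adduct="[M+Na]+", polarity="positive",
                  keep=lambda f: True, extra_peaks=(), prec_shift_ppm=0.0,
                  intensity=800.0):
    frags = [f for f in predict_fragments(species, adduct, polarity) if keep(f)]
    prec = adduct_mz(species_formula(species), adduct)
    prec *= 1 + prec_shift_ppm * 1e-6
    peaks = [(f.mz, intensity) for f in frags] + list(extra_peaks)
    return CentroidSpectrum(
        precursor_mz=prec, rt=12.0, polarity=polarity, peaks=tuple(peaks),
        precursor_intensity=1e5, spectrum_id="t")


class TestPredictFragments:
    def test_intact_ooh_fragment_retains_oxygen(self):
        ox = parse_lipid_name("TG 18:1/18:1/18:2<OOH>")
        frags = predict_fragments(ox, "[M+Na]+", "positive")
        by_desc = {f.descriptor: f for f in frags}
        assert by_desc["[FA18:2<OOH>+Na]+"].retains_added_oxygen
        assert by_desc["[FA18:2<OOH>-H2O+Na]+"].retains_added_oxygen

    def test_hydroxyl_water_loss_does_not_retain(self):
        ox = parse_lipid_name("TG 18:1/18:1/18:2<OH>")
        frags = predict_fragments(ox, "[M+Na]+", "positive")
        by_desc = {f.descriptor: f for f in frags}
        assert by_desc["[FA18:2<OH>+H]+"].retains_added_oxygen
        assert not by_desc["[FA18:2<OH>-H2O+H]+"].retains_added_oxygen

    def test_negative_mode_phospholipid_fragments(self):
        ox = parse_lipid_name("PC 16:0/18:2<OOH>")
        frags = predict_fragments(ox, "[M-H]-", "negative")
        by_desc = {f.descriptor: f for f in frags}
        assert by_desc["[FA18:2<OOH>-H]-"].retains_added_oxygen
        ox_oh = parse_lipid_name("PC 16:0/18:2<OH>")
        frags_oh = predict_fragments(ox_oh, "[M-H]-", "negative")
        by_desc_oh = {f.descriptor: f for f in frags_oh}
        assert not by_desc_oh["[FA18:2<OH>-H2O-H]-"].retains_added_oxygen

    def test_unmodified_species_rejected(self):
        with pytest.raises(UnmodifiedSpecies):
            predict_fragments(parse_lipid_name("TG 18:1/18:1/18:1"))

    def test_retention_agrees_with_accounting_oracle(self, oxidized_candidates):
        for sp in oxidized_candidates:
            for frag in predict_fragments(sp):
                if frag.origin not in ("intact-oxfa", "oxfa-water-loss"):
                    continue
                mods = sp.all_modifications
                waters = 1 if frag.origin == "oxfa-water-loss" else 0
                assert frag.retains_added_oxygen == oxygen_accounting_oracle(mods, waters), frag


class TestMatchSpectrum:
    def test_planted_candidate_scores_high_and_ranks_first(self, oxidized_candidates):
        rng = np.random.default_rng(7)
        target = oxidized_candidates[10]
        frags = predict_fragments(target)
        keep_ids = set(rng.choice(len(frags), size=max(1, int(0.9 * len(frags))),
                                  replace=False))
        spec = _spectrum_for(target, keep=lambda f: True)
        ids = match_spectrum(spec, oxidized_candidates)
        assert ids and ids[0].score > 60
        assert str(species_formula(ids[0].species)) == str(species_formula(target))

    def test_precursor_off_by_50ppm_matches_nothing(self, oxidized_candidates):
        spec = _spectrum_for(oxidized_candidates[0], prec_shift_ppm=50.0)
        assert match_spectrum(spec, oxidized_candidates) == []

    def test_subpercent_peaks_ignored_in_scoring(self, oxidized_candidates):
        target = oxidized_candidates[3]
        # decoy peak at 0.5% of base: must not dilute the score
        weak = ((200.1234, 4.0),)
        spec_clean = _spectrum_for(target)
        spec_weak = _spectrum_for(target, extra_peaks=weak)
        s1 = match_spectrum(spec_clean, [target])[0].score
        s2 = match_spectrum(spec_weak, [target])[0].score
        assert s1 == pytest.approx(s2)

    def test_low_precursor_intensity_rejected(self, oxidized_candidates):
        target = oxidized_candidates[0]
        frags = predict_fragments(target)
        spec = CentroidSpectrum(
            precursor_mz=adduct_mz(species_formula(target), "[M+Na]+"),
            rt=1.0, polarity="positive",
            peaks=tuple((f.mz, 100.0) for f in frags),
            precursor_intensity=10.0)
        assert match_spectrum(spec, [target]) == []

    def test_candidate_order_invariance(self, oxidized_candidates):
        spec = _spectrum_for(oxidized_candidates[5])
        a = match_spectrum(spec, oxidized_candidates)
        b = match_spectrum(spec, list(reversed(oxidized_candidates)))
        assert [(i.species.name(), i.score) for i in a] == \
               [(i.species.name(), i.score) for i in b]


class TestOxfaEvidenceFilter:
    def test_nonretaining_evidence_only_is_rejected(self):
        ox = parse_lipid_name("TG 18:1/18:1/18:2<OH>")
        spec = _spectrum_for(ox, keep=lambda f: not f.retains_added_oxygen)
        ids = oxfa_evidence_filter(match_spectrum(spec, [ox]))
        assert ids and not ids[0].accepted
        assert "no_oxfa_fragment" in ids[0].reasons

    def test_single_retaining_fragment_suffices(self):
        ox = parse_lipid_name("TG 18:1/18:1/18:2<OOH>")
        spec = _spectrum_for(
            ox, keep=lambda f: f.descriptor == "[FA18:2<OOH>-H2O+H]+")
        ids = oxfa_evidence_filter(match_spectrum(spec, [ox]))
        accepted = [i for i in ids if i.accepted]
        assert accepted and any(
            a.retains_added_oxygen for a in accepted[0].matched)

    def test_empty_input(self):
        assert oxfa_evidence_filter([]) == []

    def test_no_accepted_output_lacks_retaining_fragment(self, oxidized_candidates):
        # filter soundness over a mixed batch
        specs = [_spectrum_for(c) for c in oxidized_candidates[:10]]
        for spec in specs:
            for ident in oxfa_evidence_filter(match_spectrum(spec, oxidized_candidates)):
                if ident.accepted:
                    assert any(a.retains_added_oxygen for a in ident.matched)


class TestKmdRtFilter:
    def test_planted_outlier_is_exactly_flagged(self):
        entries, truth = simulate_kmd_rt_series(seed=3)
        assert kmd_rt_filter(entries) == truth

    def test_collinear_series_unflagged(self):
        entries, truth = simulate_kmd_rt_series(seed=5, outlier_sigma_mult=0.0)
        assert kmd_rt_filter(entries) == [False] * len(entries)

    def test_small_groups_pass_unflagged(self):
        entries, _ = simulate_kmd_rt_series(seed=1, n_inliers=1)
        assert kmd_rt_filter(entries) == [False, False]


class TestCollapseIsomers:
    def _ident(self, species, score):
        mz = adduct_mz(species_formula(species), "[M+Na]+")
        from epilipid.identification import Identification
        return Identification(
            spectrum_id="s", species=species, adduct="[M+Na]+",
            precursor_mz=mz, rt=10.0, matched=(), score=score,
            isotope_score=100.0, rank_score=100.0, accepted=True)

    def test_identical_formula_collapses(self):
        a = self._ident(parse_lipid_name("TG 52:3<OOH>"), 90.0)
        b = self._ident(parse_lipid_name("TG 52:3<2OH>"), 80.0)
        out = collapse_isomers([a, b])
        assert len(out) == 1 and out[0].score == 90.0

    def test_tolerance_boundary(self):
        a = self._ident(parse_lipid_name("TG 52:3<OOH>"), 90.0)
        from dataclasses import replace
        close = replace(a, precursor_mz=a.precursor_mz * (1 + 4e-6))
        far = replace(a, precursor_mz=a.precursor_mz * (1 + 20e-6))
        assert len(collapse_isomers([a, close], mz_tol_ppm=5.0)) == 1
        assert len(collapse_isomers([a, far], mz_tol_ppm=5.0)) == 2

    def test_distinct_formula_count_preserved(self, oxidized_candidates):
        # one representative per distinct precursor m/z
        idents = [self._ident(c, 50.0) for c in oxidized_candidates]
        out = collapse_isomers(idents)
        mzs = sorted(i.precursor_mz for i in out)
        assert all((b - a) / a * 1e6 > 5.0 for a, b in zip(mzs, mzs[1:]))
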