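"""Synthetic-spectrum generator and the rule-based pairing oracle."""

import numpy as np
import pytest

from fucotype.features import ExtractionParams, extract_features
from fucotype.glycan import (
    B_FUC_IONS,
    DIAGNOSTIC_ION_ORDER,
    Y_FUC_IONS,
    GlycanComposition,
    GlycopeptideID,
)
from fucotype.spectra import CLASS_ORDER
from fucotype.synthetic import (
    CORE_LIKE_COMPOSITIONS,
    DEFAULT_PEPTIDE_POOL,
    OUTER_LIKE_COMPOSITIONS,
    ClassTemplate,
    default_templates,
    generate_dataset,
    generate_gsm,
    noiseless_templates,
    oracle_classify,
)

IDX = {l: i for i, l in enumerate(DIAGNOSTIC_ION_ORDER)}
N_FUC = {"none": 0, "core": 1, "outer": 1, "dual": 2}


class TestTemplates:
    def test_default_panels_follow_pairing_logic(self):
        t = default_templates()
        assert not t["none"].present_ions & (set(B_FUC_IONS) | set(Y_FUC_IONS))
        assert set(Y_FUC_IONS) <= t["core"].present_ions
        assert not t["core"].present_ions & set(B_FUC_IONS)
        assert set(B_FUC_IONS) <= t["outer"].present_ions
        assert not t["outer"].present_ions & set(Y_FUC_IONS)
        assert (set(B_FUC_IONS) | set(Y_FUC_IONS)) <= t["dual"].present_ions

    def test_inconsistent_template_rejected(self):
        with pytest.raises(ValueError, match="core"):
            ClassTemplate(label="core", present_ions=frozenset({"B2F", "Y1"}))

    def test_unfucosylated_composition_rejected_for_fuc_templates(self):
        gp = GlycopeptideID("NEEYNK", GlycanComposition(5, 4, 0, 1))
        with pytest.raises(ValueError, match="n_fuc"):
            generate_gsm(default_templates()["core"], gp, seed=0)


class TestGenerateGsm:
    def test_deterministic_per_seed(self):
        gp = GlycopeptideID("NEEYNK", GlycanComposition(5, 4, 1, 1))
        s1, _ = generate_gsm(default_templates()["core"], gp, seed=7)
        s2, _ = generate_gsm(default_templates()["core"], gp, seed=7)
        assert s1.peaks == s2.peaks

    def test_core_spectrum_shows_only_y_series_fucose(self):
        gp = GlycopeptideID("NEEYNK", GlycanComposition(5, 4, 1, 1))
        s, _ = generate_gsm(noiseless_templates()["core"], gp, seed=0)
        v = extract_features(s, gp, ExtractionParams(snr_min=0.0)).values
        assert all(v[IDX[l]] > 0 for l in Y_FUC_IONS)
        assert all(v[IDX[l]] == 0 for l in B_FUC_IONS)

    def test_none_spectrum_has_no_fucose_ions(self):
        gp = GlycopeptideID("NEEYNK", GlycanComposition(5, 4, 0, 1))
        s, _ = generate_gsm(noiseless_templates()["none"], gp, seed=0)
        v = extract_features(s, gp, ExtractionParams(snr_min=0.0)).values
        assert all(v[IDX[l]] == 0 for l in B_FUC_IONS + Y_FUC_IONS)


class TestGeneratorOracleClosure:
    @pytest.mark.parametrize("label", CLASS_ORDER)
    def test_noiseless_spectra_recover_template_label(self, label):
        """Exhaustive closure over the peptide pool x composition grid.

        Noiseless spectra contain signal peaks only (no noise population),
        so extraction runs without the S/N gate, which is defined relative
        to a noise floor these spectra deliberately lack.
        """
        template = noiseless_templates()[label]
        params = ExtractionParams(snr_min=0.0)
        for peptide in DEFAULT_PEPTIDE_POOL:
            for h, n, s in CORE_LIKE_COMPOSITIONS + OUTER_LIKE_COMPOSITIONS:
                gp = GlycopeptideID(
                    peptide, GlycanComposition(h, n, N_FUC[label], s))
                spectrum, gsm = generate_gsm(template, gp, seed=0)
                fv = extract_features(spectrum, gp, params)
                assert oracle_classify(fv) == label == gsm.manual_label


class TestGenerateDataset:
    def test_counts_and_rows(self):
        spectra, gsms = generate_dataset(n_per_class=25, class_mix=None, seed=0)
        assert len(spectra) == 100 and len(gsms) == 100
        labels = [g.manual_label for g in gsms]
        assert all(labels.count(c) == 25 for c in CLASS_ORDER)

    def test_default_mix_is_curated_proportions(self):
        _, gsms = generate_dataset(n_per_class=100, seed=0)
        labels = [g.manual_label for g in gsms]
        assert labels.count("none") == 156  # 39% of 400
        assert labels.count("dual") == 60

    def test_degenerate_mix_gives_single_class(self):
        _, gsms = generate_dataset(n_per_class=5, class_mix=(1, 0, 0, 0), seed=0)
        assert {g.manual_label for g in gsms} == {"none"}

    def test_titles_unique(self):
        spectra, _ = generate_dataset(n_per_class=10, seed=0)
        titles = [s.title for s in spectra]
        assert len(set(titles)) == len(titles)

    def test_empty_peptide_pool_rejected(self):
        with pytest.raises(ValueError, match="peptide"):
            generate_dataset(n_per_class=1, peptides=[])

    def test_oracle_agrees_with_hidden_labels_at_default_noise(self):
        spectra, gsms = generate_dataset(n_per_class=50, seed=5)
        hits = 0
        for s, g in zip(spectra, gsms):
            fv = extract_features(s, g.glycopeptide)
            hits += oracle_classify(fv) == g.manual_label
        assert hits / len(gsms) >= 0.95


class TestOracle:
    def test_b_series_fucose_is_outer(self):
        v = np.zeros(14)
        v[IDX["B3SF"]] = 0.3
        assert oracle_classify(v) == "outer"

    def test_y_series_fucose_is_core(self):
        v = np.zeros(14)
        v[IDX["Y1F"]] = 0.2
        assert oracle_classify(v) == "core"

    def test_both_groups_are_dual(self):
        v = np.zeros(14)
        v[IDX["B2F"]] = v[IDX["Y2F"]] = 0.2
        assert oracle_classify(v) == "dual"

    def test_all_zero_is_none(self):
        assert oracle_classify(np.zeros(14)) == "none"

    def test_threshold_suppresses_weak_evidence(self):
        v = np.zeros(14)
        v[IDX["B2F"]] = 0.05
        assert oracle_classify(v, threshold=0.1) == "none"
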