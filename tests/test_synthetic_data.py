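"""Synthetic-data generator: determinism, ground-truth consistency, packing,
cohort effect structure, and the protein-matrix generator."""

import numpy as np
import pytest

from isletmorph import (
    CohortParams,
    MatrixParams,
    PackingError,
    SectionParams,
    compare_groups,
    generate_cohort,
    generate_protein_matrix,
    generate_section,
)

NULL_MULTIPLIERS = {
    "islet_area": 1.0,
    "alpha_area": 1.0,
    "beta_area": 1.0,
    "bihormonal_area": 1.0,
    "marker_area": 1.0,
    "marker_intensity": 1.0,
}


class TestGenerateSection:
    def test_fixed_seed_bit_identical(self):
        s1, t1 = generate_section(SectionParams(seed=7))
        s2, t2 = generate_section(SectionParams(seed=7))
        for name in s1.channels:
            assert np.array_equal(s1.channels[name], s2.channels[name])
        assert np.array_equal(t1.islet_labels, t2.islet_labels)
        assert t1.areas == t2.areas

    def test_no_islets_blank_hormone_channels(self):
        section, truth = generate_section(
            SectionParams(n_islets=0, noise_sd=0, seed=0)
        )
        for name in ("islet", "alpha", "beta", "bihormonal", "marker"):
            assert truth.areas[name] == 0.0
        bg = SectionParams().background_level
        assert section.channel("glucagon").max() == bg
        assert section.channel("insulin").max() == bg

    def test_truth_areas_equal_pixel_counts(self, clean_section):
        """Every reported true area equals mask pixel count x pixel_size^2."""
        _, truth = clean_section
        px2 = truth.pixel_size**2
        for name, mask in truth.masks.items():
            assert truth.areas[name] == mask.sum() * px2
        assert not (truth.masks["alpha"] & truth.masks["beta"]).any()
        union = (
            truth.masks["alpha"] | truth.masks["beta"] | truth.masks["bihormonal"]
        )
        assert np.array_equal(union, truth.masks["islet"])
        assert np.array_equal(truth.masks["islet"], truth.islet_labels > 0)

    def test_truth_consistent_with_noise_free_render(self, clean_section):
        """Rendered hormone channels binarise exactly to the truth masks."""
        section, truth = clean_section
        glucagon_pos = section.channel("glucagon") > 100
        insulin_pos = section.channel("insulin") > 100
        assert np.array_equal(
            glucagon_pos, truth.masks["alpha"] | truth.masks["bihormonal"]
        )
        assert np.array_equal(
            insulin_pos, truth.masks["beta"] | truth.masks["bihormonal"]
        )

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_section(SectionParams(width=200, height=200, n_islets=30))

    def test_nuclei_respect_minimum_spacing(self, clean_section):
        _, truth = clean_section
        xy = np.concatenate(list(truth.nuclei_centres.values()))
        from scipy.spatial import cKDTree

        d, _ = cKDTree(xy).query(xy, k=2)
        min_sep_px = 2.5 * SectionParams().nucleus_radius / truth.pixel_size
        assert d[:, 1].min() >= min_sep_px - 1e-9

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SectionParams(alpha_fraction=0.6, beta_fraction=0.6)
        with pytest.raises(ValueError):
            SectionParams(pixel_size=0.0)
        with pytest.raises(ValueError):
            SectionParams(islet_radius_range=(10.0, 5.0))
        with pytest.raises(ValueError):
            SectionParams(nuclei_density=50.0)  # denser than nuclei can pack


class TestGenerateCohort:
    def test_structure_and_determinism(self):
        cohort = CohortParams(n_per_group=2, seed=3)
        base = SectionParams(width=256, height=256, n_islets=1,
                             islet_radius_range=(30, 34), nuclei_density=2.0)
        r1 = generate_cohort(cohort, base)
        r2 = generate_cohort(cohort, base)
        assert [x.group for x in r1] == ["control"] * 2 + ["pregnant"] * 2
        assert len({x.donor_id for x in r1}) == 4
        for a, b in zip(r1, r2):
            assert np.array_equal(
                a.section.channel("insulin"), b.section.channel("insulin")
            )

    def test_non_positive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(multipliers={"islet_area": 0.0})
        with pytest.raises(ValueError):
            CohortParams(n_per_group=1)

    def test_null_cohort_rejects_at_nominal_rate(self):
        """Multipliers of 1 make groups exchangeable: over 200 cohorts the
        t-test on true islet fractional area rejects in 5% +/- 2%."""
        base = SectionParams(width=256, height=256, n_islets=2,
                             islet_radius_range=(30, 34), nuclei_density=2.0,
                             noise_sd=0)
        rejections = 0
        n_cohorts = 200
        for seed in range(n_cohorts):
            rec = generate_cohort(
                CohortParams(n_per_group=5, multipliers=NULL_MULTIPLIERS,
                             cv=0.25, seed=seed),
                base,
            )
            vals = {"pregnant": [], "control": []}
            for r in rec:
                vals[r.group].append(
                    100 * r.truth.areas["islet"] / r.truth.areas["tissue"]
                )
            res = compare_groups(vals["pregnant"], vals["control"], policy="force_t")
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_cohorts <= 0.07

    def test_effect_multipliers_scale_truth_areas(self):
        """Averaged over donors, pregnant/control truth area ratios approach
        the design folds for alpha and beta."""
        base = SectionParams(width=384, height=384, n_islets=2,
                             islet_radius_range=(36, 40), nuclei_density=2.0,
                             noise_sd=0)
        ratios = {"alpha": [], "beta": []}
        for seed in range(25):
            rec = generate_cohort(CohortParams(n_per_group=4, cv=0.1, seed=seed), base)
            sums = {g: {k: 0.0 for k in ratios} for g in ("pregnant", "control")}
            for r in rec:
                for k in ratios:
                    sums[r.group][k] += r.truth.areas[k] / r.truth.areas["tissue"]
            for k in ratios:
                ratios[k].append(sums["pregnant"][k] / sums["control"][k])
        assert np.mean(ratios["alpha"]) == pytest.approx(4.3, rel=0.12)
        assert np.mean(ratios["beta"]) == pytest.approx(1.9, rel=0.12)


class TestGenerateProteinMatrix:
    def test_complete_null_matrix(self):
        pm, truth = generate_protein_matrix(
            MatrixParams(n_proteins=50, missing_rate=0.0, n_true_effects=0, seed=0)
        )
        assert pm.data.notna().all().all()
        assert not truth["spiked"].any()
        assert pm.data.shape == (50, 12)

    def test_spike_recovered_within_three_sem(self):
        params = MatrixParams(n_proteins=200, n_true_effects=40,
                              effect_size=1.5, seed=8)
        pm, truth = generate_protein_matrix(params)
        preg = pm.samples_in("pregnant_islet")
        ctrl = pm.samples_in("control_islet")
        diffs = (
            pm.data.loc[truth["spiked"], preg].mean(axis=1)
            - pm.data.loc[truth["spiked"], ctrl].mean(axis=1)
        )
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - params.effect_size) < 3 * sem

    def test_missing_rate_realised(self):
        pm, _ = generate_protein_matrix(
            MatrixParams(n_proteins=500, missing_rate=0.2, seed=1)
        )
        assert pm.data.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.02)

    def test_fixed_seed_determinism(self):
        p = MatrixParams(n_proteins=30, n_true_effects=5, missing_rate=0.1, seed=5)
        m1, t1 = generate_protein_matrix(p)
        m2, t2 = generate_protein_matrix(p)
        assert m1.data.equals(m2.data)
        assert t1.equals(t2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MatrixParams(missing_rate=1.0)
        with pytest.raises(ValueError):
            MatrixParams(n_true_effects=10, n_proteins=5)


def test_cohort_fold_change_recovery_monte_carlo():
    """Islet-area multiplier 1.9 alone, n = 7+7, donor CV 0.25: the
    pipeline-estimated islet fractional-area fold change lands within 25%
    of 1.9 in at least 90% of 100 replicate cohorts."""
    from isletmorph import analyze_section

    multipliers = {"islet_area": 1.9}
    hits = 0
    n_cohorts = 100
    for seed in range(n_cohorts):
        rec = generate_cohort(CohortParams(multipliers=multipliers, seed=seed))
        vals = {"pregnant": [], "control": []}
        for r in rec:
            metrics, _ = analyze_section(r.section, include_nuclei=False)
            vals[r.group].append(metrics["islet_fractional_area_pct"])
        fold = np.mean(vals["pregnant"]) / np.mean(vals["control"])
        hits += abs(fold - 1.9) <= 0.25 * 1.9
    assert hits / n_cohorts >= 0.90
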