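import numpy as np
import pandas as pd
import pytest

from spoteval.io_model import ValidationError
from spoteval.preprocess import log10_transform, normalize_sum
from spoteval.stats import (
    AssayError,
    bca_apply,
    bca_concentration,
    bca_fit,
    pca_overview,
    split_by_extraction_mode,
    volcano,
)
from spoteval.synthetic import (
    SyntheticConfig,
    default_class_yield,
    generate_consecutive_pair,
)
from conftest import make_table

PLATE_STANDARDS = [0.0, 25.0, 125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0]


def pair_tables(seed=0, noise_cv=0.1, boost=None, n_features=6, class_yield=None):
    cfg = SyntheticConfig(
        n_features_per_class=n_features,
        class_yield=class_yield
        or default_class_yield(classes=["sugars", "TG"], devices=["Capitainer"]),
        noise_cv=noise_cv,
        detection_limit=0.0,
        decay_rate={},
        n_replicates=3,
        seed=seed,
    )
    table, _ = generate_consecutive_pair(cfg, boost=boost or {})
    single, consec = split_by_extraction_mode(table)
    return normalize_sum(single), normalize_sum(consec)


class TestVolcano:
    def test_identical_groups_not_significant(self):
        single, _ = pair_tables(boost={})
        res = volcano(single, single)
        assert np.allclose(res.table["log2fc"], 0.0)
        assert np.allclose(res.table["pvalue"], 1.0)
        assert not res.table["significant"].any()

    def test_boosted_class_recovered(self):
        # boosted class kept a minor share of total signal so the sum
        # normalization barely dilutes the 4x gain
        cy = {("sugars", "CH3OH100", "Capitainer"): 0.05,
              ("TG", "CH3OH100", "Capitainer"): 0.95}
        single, consec = pair_tables(seed=3, noise_cv=0.05,
                                     boost={"sugars": 4.0}, class_yield=cy)
        res = volcano(single, consec)
        sugars = res.table["compound_class"] == "sugars"
        assert res.table.loc[sugars, "significant"].all()
        assert res.table.loc[sugars, "log2fc"].mean() == pytest.approx(2.0, abs=0.5)
        tg = res.table["compound_class"] == "TG"
        assert res.table.loc[tg, "log2fc"].mean() < 0  # pushed down by the sum shift

    def test_group_swap_symmetry(self):
        single, consec = pair_tables(seed=4, boost={"sugars": 2.0})
        fwd = volcano(single, consec)
        rev = volcano(consec, single)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])
        assert np.allclose(fwd.table["pvalue"], rev.table["pvalue"])
        assert (fwd.table["significant"] == rev.table["significant"]).all()

    def test_requires_normalized_inputs(self):
        cfg = SyntheticConfig(
            n_features_per_class=2,
            class_yield=default_class_yield(classes=["sugars"], devices=["Capitainer"]),
            detection_limit=0.0, seed=1,
        )
        table, _ = generate_consecutive_pair(cfg, boost={})
        single, consec = split_by_extraction_mode(table)
        with pytest.raises(ValidationError, match="normalized"):
            volcano(single, consec)

    def test_both_zero_features_excluded(self):
        raw = np.array([[1.0, 2.0, 1.5, 1.2], [0.0, 0.0, 0.0, 0.0],
                        [2.0, 1.0, 1.5, 1.8]])
        meta_s = [(f"S{r}", "Capitainer", "CH3OH100", r, 0, "both", "single")
                  for r in (1, 2)]
        meta_c = [(f"C{r}", "Capitainer", "CH3OH100", r, 0, "both", "consecutive")
                  for r in (1, 2)]
        feats = [("a", "polar", "sugars"), ("b", "polar", "sugars"), ("c", "polar", "sugars")]
        s = normalize_sum(make_table(raw[:, :2], feats, meta_s))
        c = normalize_sum(make_table(raw[:, 2:], feats, meta_c))
        res = volcano(s, c)
        assert res.excluded == ["b"]
        assert list(res.table.index) == ["a", "c"]


class TestPca:
    def test_rank_one_data_pc1_100(self):
        rng = np.random.default_rng(0)
        loading = rng.normal(size=5)
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer(loading, scores) + 10.0
        meta = [(f"S{j}", "Capitainer", "CH3OH100", j + 1, 0, "both", "single")
                for j in range(4)]
        t = make_table(X - X.min() + 1.0, [(f"f{i}", "polar", "sugars") for i in range(5)],
                       meta, normalized=True, log_transformed=True)
        res = pca_overview(t)
        assert res.variance_explained_pct.iloc[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self):
        rng = np.random.default_rng(1)
        meta = [(f"S{j}", "Capitainer", "CH3OH100", j + 1, 0, "both", "single")
                for j in range(6)]
        t = make_table(rng.lognormal(6, 1, size=(10, 6)),
                       [(f"f{i}", "polar", "sugars") for i in range(10)], meta)
        res = pca_overview(log10_transform(normalize_sum(t)))
        assert res.variance_explained_pct.sum() == pytest.approx(100.0)
        assert res.pc12_sum_pct == pytest.approx(res.variance_explained_pct.iloc[:2].sum())

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        meta = [(f"S{j}", "Capitainer", "CH3OH100", j + 1, 0, "both", "single")
                for j in range(5)]
        t = make_table(rng.lognormal(6, 1, size=(8, 5)),
                       [(f"f{i}", "polar", "sugars") for i in range(8)], meta)
        t = log10_transform(normalize_sum(t))
        shuffled = t.subset_samples(["S3", "S1", "S0", "S2", "S4"])
        a = pca_overview(t).variance_explained_pct
        b = pca_overview(shuffled).variance_explained_pct
        assert np.allclose(a, b)

    def test_well_separated_clusters_split_on_pc1(self):
        """Two solvent groups with a large yield gap separate along PC1."""
        rng = np.random.default_rng(3)
        base = rng.lognormal(10, 1, size=20)
        cols, meta = [], []
        for j in range(3):
            cols.append(base * rng.lognormal(0, 0.05, size=20))
            meta.append((f"A{j}", "Capitainer", "CH3OH100", j + 1, 0, "both", "single"))
        for j in range(3):
            shifted = base.copy()
            shifted[:10] *= 10.0  # half the features extracted 10x better
            cols.append(shifted * rng.lognormal(0, 0.05, size=20))
            meta.append((f"B{j}", "Capitainer", "ISO", j + 1, 0, "both", "single"))
        t = make_table(np.column_stack(cols),
                       [(f"f{i}", "polar", "sugars") for i in range(20)], meta)
        res = pca_overview(log10_transform(normalize_sum(t)))
        pc1 = res.scores["PC1"]
        assert pc1[:3].max() < pc1[3:].min() or pc1[:3].min() > pc1[3:].max()

    def test_constant_matrix_rejected(self):
        meta = [(f"S{j}", "Capitainer", "CH3OH100", j + 1, 0, "both", "single")
                for j in range(3)]
        t = make_table(np.full((4, 3), 7.0),
                       [(f"f{i}", "polar", "sugars") for i in range(4)], meta)
        with pytest.raises(ValidationError, match="constant"):
            pca_overview(t)


class TestBca:
    def test_exact_inversion_on_linear_standards(self):
        fit = bca_fit([(c, 0.001 * c) for c in PLATE_STANDARDS])
        assert fit.slope == pytest.approx(0.001)
        assert fit.r_squared == pytest.approx(1.0)
        est = bca_concentration(fit, 0.5)
        assert est.concentration_ug_ml == pytest.approx(500.0)
        assert not est.extrapolated

    def test_dilution_factor_scales_linearly(self):
        fit = bca_fit([(c, 0.001 * c) for c in PLATE_STANDARDS])
        assert bca_concentration(fit, 0.5, dilution_factor=2).concentration_ug_ml == \
            pytest.approx(1000.0)

    def test_extrapolation_flagged_above_top_standard(self):
        fit = bca_fit([(c, 0.001 * c) for c in PLATE_STANDARDS])
        assert bca_concentration(fit, 2.5).extrapolated

    def test_negative_slope_is_assay_failure(self):
        with pytest.raises(AssayError, match="slope"):
            bca_fit([(0.0, 1.0), (1000.0, 0.2), (2000.0, 0.05)])

    def test_noisy_fit_within_residual_bounds(self):
        rng = np.random.default_rng(6)
        conc = np.array(PLATE_STANDARDS)
        ab = 0.0008 * conc + 0.05 + rng.normal(0, 0.01, size=conc.size)
        fit = bca_fit(np.column_stack([conc, ab]))
        # inversion error of a standard equals its fit residual over the slope
        resid_c = np.abs(ab - np.polyval(fit.coeffs, conc)) / fit.slope
        for c, a, bound in zip(conc, ab, resid_c):
            err = abs(bca_concentration(fit, a).concentration_ug_ml - c)
            assert err <= bound + 1e-9

    def test_quadratic_fit_inverts_curved_standards(self):
        conc = np.array(PLATE_STANDARDS)
        ab = 0.001 * conc - 5e-8 * conc**2  # mild top-of-range curvature
        fit = bca_fit(np.column_stack([conc, ab]), degree=2)
        for c, a in zip(conc, ab):
            assert bca_concentration(fit, a).concentration_ug_ml == pytest.approx(c, abs=1e-6)

    def test_apply_to_plate(self):
        std = pd.DataFrame({"concentration_ug_ml": PLATE_STANDARDS,
                            "absorbance": [0.001 * c for c in PLATE_STANDARDS]})
        from spoteval.io_model import BcaPlate
        unk = pd.DataFrame({"sample_id": ["u1", "u2"], "absorbance": [0.1, 1.0],
                            "dilution_factor": [1.0, 5.0]})
        out = bca_apply(bca_fit(std), BcaPlate(std, unk))
        assert out["concentration_ug_ml"].tolist() == pytest.approx([100.0, 5000.0])
        assert out["extrapolated"].tolist() == [False, False]
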