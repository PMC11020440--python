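"""Linear model assembly, fitting, rescalings and z-score interpretation."""

import numpy as np
import pandas as pd
import pytest

from varfit.alignment_features import (
    SubstitutionMatrix,
    Variant,
    regularized_frequencies,
)
from varfit.coevolution import SequenceWeights, fit_potts_plm
from varfit.fitness_model import (
    EVOLUTIONARY_BLOCK,
    FEATURES,
    STRUCTURAL_BLOCK,
    Coefficients,
    FeatureVector,
    TrainingSet,
    assemble_features,
    decompose,
    fit_coefficients,
    fitness_score,
    impute_missing,
    per_residue_summary,
    rescaled_pop,
    rescaled_snp,
    subset_mean,
    zscores,
)
from varfit.synthetic_data import DEFAULT_TRUE_ALPHA, make_synthetic_dms

from conftest import msa_from_strings


def random_coefficients(rng) -> Coefficients:
    return Coefficients(
        alpha=rng.normal(size=9), beta=rng.normal(size=2), gamma=rng.normal(size=2)
    )


def random_feature_vector(rng) -> FeatureVector:
    values = rng.normal(size=8)
    values[5] = abs(values[5])  # CI >= 0
    return FeatureVector(**dict(zip(FEATURES, values)))


class TestFeatureVector:
    def test_mask_reports_availability(self):
        fv = FeatureVector(RSA=10.0, CI=0.2)
        assert fv.mask["RSA"] and fv.mask["CI"]
        assert not fv.mask["PoP"]

    def test_as_array_requires_completeness(self):
        with pytest.raises(ValueError, match="PoP"):
            FeatureVector(RSA=1.0).as_array()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(RSA=np.nan)

    def test_negative_ci_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(CI=-0.1)


class TestAssembleFeatures:
    @pytest.fixture
    def sources(self):
        msa = msa_from_strings(["ACDEF", "ACDEF", "AVDE-", "GCD-F", "ACNEF"])
        freq = regularized_frequencies(msa)
        potts = fit_potts_plm(msa, SequenceWeights(np.ones(5), 1.0))
        return freq, potts

    def test_all_sources_full_mask(self, sources, tmp_path):
        freq, potts = sources
        from varfit.structure_features import load_feature_table
        p = tmp_path / "ext.csv"
        p.write_text("variant,PoP,MAE,SNP\nC2W,1.0,2.0,3.0\n")
        fv = assemble_features(
            Variant(2, "C", "W"), frequencies=freq, potts=potts,
            substitution_matrix=SubstitutionMatrix.from_name("BLOSUM62"),
            rsa_by_position={2: 45.0}, external=load_feature_table(p),
        )
        assert all(fv.mask.values())
        assert fv.RSA == 45.0 and fv.PoP == 1.0

    def test_no_external_table_leaves_structural_absent(self, sources):
        freq, potts = sources
        fv = assemble_features(Variant(2, "C", "W"), frequencies=freq, potts=potts)
        assert fv.mask["CI"] and fv.mask["LOR"] and fv.mask["PVS"] and fv.mask["PYF"]
        assert not (fv.mask["PoP"] or fv.mask["MAE"] or fv.mask["SNP"])

    def test_uncovered_column_flagged_but_vector_produced(self):
        msa = msa_from_strings(["ACD", "A-D", "A-D", "G-E"])
        freq = regularized_frequencies(msa)
        potts = fit_potts_plm(msa, SequenceWeights(np.ones(4), 1.0))
        fv = assemble_features(Variant(2, "C", "W"), frequencies=freq, potts=potts)
        assert "PVS_uncovered" in fv.flags and "PYF_uncovered" in fv.flags
        assert fv.PVS == 0.0 and fv.PYF == 0.0


class TestImputeMissing:
    def test_complete_table_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 8)), columns=list(FEATURES))
        out, mask = impute_missing(df)
        pd.testing.assert_frame_equal(out, df)
        assert not mask.to_numpy().any()

    def test_median_of_three(self):
        df = pd.DataFrame({f: [1.0, 2.0, 3.0, 4.0] for f in FEATURES})
        df.loc[3, "PoP"] = np.nan
        df.loc[3, [f for f in FEATURES if f != "PoP"]] = 0.0
        out, mask = impute_missing(df)
        assert out.loc[3, "PoP"] == 2.0  # median of {1, 2, 3}
        assert mask.loc[3, "PoP"]

    def test_random_pattern_matches_median_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 8)), columns=list(FEATURES))
        holes = rng.random(size=df.shape) < 0.2
        holes[:, 0] &= ~holes[:, 0].all()  # keep at least one value
        df_holed = df.mask(holes)
        out, _ = impute_missing(df_holed)
        for j, f in enumerate(FEATURES):
            med = np.median(df_holed[f].dropna())
            for i in range(30):
                expected = med if holes[i, j] else df.iloc[i, j]
                assert out.loc[i, f] == pytest.approx(expected)

    def test_fully_absent_feature_named(self):
        df = pd.DataFrame({f: [1.0, 2.0] for f in FEATURES})
        df["MAE"] = np.nan
        with pytest.raises(ValueError, match="MAE"):
            impute_missing(df)


class TestFitnessScore:
    def test_intercept_only_neutral(self, rng):
        coef = Coefficients(alpha=np.r_[np.zeros(8), 1.0])
        for _ in range(5):
            assert fitness_score(random_feature_vector(rng), coef) == 1.0

    def test_linearity_in_coefficients(self, rng):
        fv = random_feature_vector(rng)
        coef = random_coefficients(rng)
        doubled = Coefficients(alpha=2 * coef.alpha)
        s = fitness_score(fv, coef)
        assert fitness_score(fv, doubled) == pytest.approx(2 * s)

    def test_dot_product_oracle(self, rng):
        for _ in range(20):
            fv = random_feature_vector(rng)
            coef = random_coefficients(rng)
            expected = float(np.dot(fv.as_array(), coef.alpha[:8]) + coef.alpha[8])
            assert fitness_score(fv, coef) == pytest.approx(expected, abs=1e-12)

    def test_absent_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            fitness_score(FeatureVector(RSA=1.0), random_coefficients(rng))


class TestFitCoefficients:
    def test_noiseless_exact_recovery(self):
        train, truth = make_synthetic_dms(n=200, seed=7, noise_sd=0.0)
        coef, diag = fit_coefficients(train)
        np.testing.assert_allclose(coef.alpha, truth.alpha, atol=1e-8)
        assert diag.residual_rms < 1e-10

    def test_evo_str_ratio_near_three(self):
        train, _ = make_synthetic_dms(n=5000, seed=1, noise_sd=0.1)
        _, diag = fit_coefficients(train)
        assert 2.0 < diag.evo_str_ratio < 4.5

    def test_coverage_of_three_standard_errors(self):
        # quick version of the recovery study: 20 replicates
        hits = 0
        total = 0
        for seed in range(20):
            train, truth = make_synthetic_dms(n=2000, seed=seed, noise_sd=0.1)
            coef, diag = fit_coefficients(train)
            within = np.abs(coef.alpha - truth.alpha) <= 3 * diag.stderr
            hits += int(within.sum())
            total += within.size
        assert hits / total >= 0.95

    def test_duplicated_feature_column_ols_error_ridge_ok(self):
        train, _ = make_synthetic_dms(n=100, seed=3, noise_sd=0.05)
        df = train.table.copy()
        df["MAE"] = df["PoP"]  # exact collinearity
        collinear = TrainingSet(df)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_coefficients(collinear, method="ols")
        coef, _ = fit_coefficients(collinear, method="ridge")
        assert np.all(np.isfinite(coef.alpha))

    def test_too_few_rows_rejected(self):
        train, _ = make_synthetic_dms(n=8, seed=0, noise_sd=0.0)
        with pytest.raises(ValueError, match="at least 9"):
            fit_coefficients(train)


class TestRescalings:
    def test_snp_identity_and_constant(self):
        ident = Coefficients(alpha=np.zeros(9), beta=np.array([1.0, 0.0]))
        assert rescaled_snp(3.7, ident) == 3.7
        const = Coefficients(alpha=np.zeros(9), beta=np.array([0.0, 5.0]))
        assert rescaled_snp(-100.0, const) == 5.0

    def test_snp_affine_oracle(self, rng):
        for _ in range(20):
            coef = random_coefficients(rng)
            x = rng.normal()
            assert rescaled_snp(x, coef) == pytest.approx(
                coef.beta[0] * x + coef.beta[1], abs=1e-12)

    @pytest.mark.parametrize("y,expected", [(-5.0, 0.0), (7.0, 1.0), (0.42, 0.42)])
    def test_pop_clamp_regions(self, y, expected):
        coef = Coefficients(alpha=np.zeros(9), gamma=np.array([1.0, 0.0]))
        assert rescaled_pop(y, coef) == pytest.approx(expected)

    def test_double_relu_equals_clamp_on_dense_grid(self, rng):
        coef = Coefficients(alpha=np.zeros(9), gamma=np.array([0.7, -0.3]))
        for x in np.linspace(-10, 10, 4001):
            y = coef.gamma[0] * x + coef.gamma[1]
            clamp = min(max(y, 0.0), 1.0)
            got = rescaled_pop(x, coef)
            assert abs(got - clamp) <= 1e-12
            assert 0.0 <= got <= 1.0


class TestDecompose:
    def test_zero_structural_features(self, rng):
        coef = random_coefficients(rng)
        fv = FeatureVector(RSA=1.0, PoP=0.0, MAE=0.0, SNP=0.0,
                           PVS=1.0, CI=1.0, LOR=1.0, PYF=1.0)
        s, e = decompose(fv, coef)
        assert s == 0.0

    def test_reconstruction_identity(self, rng):
        for _ in range(50):
            fv = random_feature_vector(rng)
            coef = random_coefficients(rng)
            s, e = decompose(fv, coef)
            total = s + e + coef.alpha[0] * fv.RSA + coef.alpha[8]
            assert total == pytest.approx(fitness_score(fv, coef), abs=1e-10)

    def test_block_sums_match_oracle(self, rng):
        fv = random_feature_vector(rng)
        coef = random_coefficients(rng)
        x = fv.as_array()
        s_oracle = sum(coef.alpha[FEATURES.index(f)] * x[FEATURES.index(f)]
                       for f in STRUCTURAL_BLOCK)
        e_oracle = sum(coef.alpha[FEATURES.index(f)] * x[FEATURES.index(f)]
                       for f in EVOLUTIONARY_BLOCK)
        s, e = decompose(fv, coef)
        assert s == pytest.approx(s_oracle) and e == pytest.approx(e_oracle)


def score_table(rng, n=40):
    df = pd.DataFrame({
        "position": np.repeat(np.arange(1, n // 4 + 1), 4)[:n],
        "score": rng.normal(size=n),
        "STR": rng.normal(size=n),
        "EVO": rng.normal(size=n),
    })
    return df


class TestZScores:
    def test_mean_zero_sd_one(self, rng):
        out = zscores(score_table(rng))
        for col in ("Z", "Z_str", "Z_evo"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        df = score_table(rng)
        out1 = zscores(df)
        df2 = df.copy()
        df2["score"] = 3.0 * df2["score"] - 7.0
        out2 = zscores(df2)
        np.testing.assert_allclose(out1["Z"], out2["Z"], atol=1e-10)

    def test_five_variant_hand_oracle(self):
        df = pd.DataFrame({
            "position": [1] * 5,
            "score": [1.0, 2.0, 3.0, 4.0, 5.0],
            "STR": [0.0, 0.0, 1.0, 1.0, 2.0],
            "EVO": [2.0, 2.0, 2.0, 2.0, 3.0],
        })
        out = zscores(df)
        np.testing.assert_allclose(
            out["Z"], (df["score"] - 3.0) / np.sqrt(2.0), atol=1e-12)
        np.testing.assert_allclose(
            out["Z_str"], (df["STR"] - 0.8) / np.sqrt(np.mean((df["STR"] - 0.8) ** 2)),
            atol=1e-12)

    def test_constant_scores_rejected(self):
        df = pd.DataFrame({"position": [1, 1], "score": [1.0, 1.0],
                           "STR": [0.0, 1.0], "EVO": [0.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            zscores(df)

    def test_subset_warns(self, rng):
        df = score_table(rng, n=20)
        with pytest.warns(UserWarning, match="full"):
            zscores(df, query_length=50)


class TestPerResidueSummary:
    def test_constant_z_gives_constant_means(self):
        df = pd.DataFrame({
            "position": [1, 1, 2, 2], "Z": [0.7] * 4,
            "Z_str": [0.7] * 4, "Z_evo": [0.7] * 4,
        })
        out = per_residue_summary(df)
        np.testing.assert_allclose(out[["Z", "Z_str", "Z_evo"]], 0.7)

    def test_group_by_oracle(self, rng):
        df = zscores(score_table(rng))
        out = per_residue_summary(df)
        for _, row in out.iterrows():
            sub = df[df["position"] == row["position"]]
            assert row["Z_evo"] == pytest.approx(sub["Z_evo"].mean())

    def test_empty_subset_mean_rejected(self, rng):
        df = zscores(score_table(rng))
        with pytest.raises(ValueError, match="empty"):
            subset_mean(df, df["score"] > 1e9)


class TestCoefficientsIO:
    def test_round_trip(self, rng, tmp_path):
        coef = Coefficients(
            alpha=rng.normal(size=9), beta=rng.normal(size=2),
            gamma=rng.normal(size=2), provenance="test fit",
            feature_medians={f: 0.5 for f in FEATURES},
        )
        p = tmp_path / "coef.json"
        coef.save(p)
        back = Coefficients.load(p)
        np.testing.assert_array_equal(back.alpha, coef.alpha)
        np.testing.assert_array_equal(back.gamma, coef.gamma)
        assert back.provenance == coef.provenance
        assert back.feature_medians == coef.feature_medians

    def test_wrong_feature_order_rejected(self, tmp_path):
        import json
        p = tmp_path / "coef.json"
        payload = {"format_version": 1, "feature_order": ["X"],
                   "alpha": [0.0] * 9, "beta": [1, 0], "gamma": [1, 0]}
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="feature order"):
            Coefficients.load(p)
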