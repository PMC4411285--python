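"""Attribute extraction, structure PCA, and Box-Cox normalisation."""

import numpy as np
import pytest
import scipy.stats as st

from pananchor import features
from pananchor.datamodel import GenomePosition
from pananchor.features import (
    PCAResult,
    _transform,
    boxcox_apply,
    boxcox_fit,
    extract_attributes,
    structure_pca,
    tag_structure_correlation,
)
from pananchor.gwas import MappingResult, map_all_gwas, map_tag_gwas
from tests.conftest import toy_matrices, toy_tags


class TestStructurePCA:
    def test_separated_subpops_split_on_pc1(self):
        n = 60
        rng = np.random.default_rng(0)
        half = np.zeros(n, bool); half[: n // 2] = True
        patterns = [half ^ (rng.random(n) < 0.02) for _ in range(80)]
        snps = toy_matrices(n, patterns=patterns, positions=list(range(1000, 81000, 1000)))
        pca = structure_pca(snps, seed=1)
        side = pca.scores[:, 0] > 0
        assert np.array_equal(side, half) or np.array_equal(side, ~half)

    def test_too_few_taxa_is_error(self):
        snps = toy_matrices(3, patterns=[np.array([1, 0, 1], bool)])
        with pytest.raises(ValueError):
            structure_pca(snps, k=3)

    def test_variance_explained_sane(self, small_panel):
        pca = structure_pca(small_panel.snps, seed=0)
        ve = pca.variance_explained
        assert ve.sum() <= 1.0 + 1e-9
        assert all(np.diff(ve) <= 1e-12)

    def test_deterministic_given_seed(self, small_panel):
        a = structure_pca(small_panel.snps, seed=5)
        b = structure_pca(small_panel.snps, seed=5)
        assert np.allclose(a.scores, b.scores)


class TestTagStructureCorrelation:
    def test_presence_matching_pc_sign_split(self):
        rng = np.random.default_rng(1)
        scores = np.column_stack([rng.standard_normal(100) for _ in range(3)])
        pca = PCAResult(scores, np.array([0.2, 0.1, 0.05]))
        presence = (scores[:, 0] > 0).astype(float)
        # point-biserial r of a median split of a normal is ~0.8
        r = tag_structure_correlation(presence, pca)
        assert r == pytest.approx(abs(st.pearsonr(presence, scores[:, 0])[0]))
        assert r > 0.7

    def test_permuted_presence_small_r(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((400, 3))
        pca = PCAResult(scores, np.array([0.1, 0.1, 0.1]))
        rs = []
        for _ in range(200):
            presence = rng.random(400) < 0.3
            rs.append(tag_structure_correlation(presence.astype(float), pca))
        assert np.quantile(rs, 0.95) < 2 * 2 / np.sqrt(400)

    def test_constant_presence_returns_zero(self):
        pca = PCAResult(np.random.default_rng(0).standard_normal((50, 3)), np.ones(3) / 10)
        assert tag_structure_correlation(np.ones(50), pca) == 0.0


class TestExtractAttributes:
    def _fixture(self):
        """5-SNP fixture with a hand-computable profile."""
        n = 200
        carriers = np.zeros(n, bool); carriers[:50] = True
        noise = np.zeros(n, bool); noise[::4] = True
        snps = toy_matrices(
            n,
            patterns=[carriers, carriers, noise, noise, carriers],
            mafs=[0.25, 0.25, 0.25, 0.25, 0.25],
            chroms=[1, 1, 1, 2, 2],
            positions=[1_000, 51_000, 200_000, 5_000, 9_000],
        )
        tags = toy_tags(snps.taxa, [carriers])
        pca = PCAResult(np.zeros((n, 3)), np.zeros(3))
        return snps, tags, pca

    def test_hand_computed_g_vector(self):
        snps, tags, pca = self._fixture()
        res = map_tag_gwas(0, tags, snps)
        att = extract_attributes(res, None, snps, tags, pca)
        v = dict(zip(att.names, att.values))
        assert att.model_class == "G"
        # best = chr1:1000 (tie with chr1:51000 and chr2:5000/9000 broken
        # by smallest global position); profile = the three perfect-LD SNPs
        assert res.pos == GenomePosition(1, 1_000)
        assert v["n_sig_snps"] == 3
        assert v["sig_span_bp"] == 50_000  # chr1: 1000..51000
        assert v["sig_frac_best_chrom"] == pytest.approx(2 / 3)
        assert v["tag_count"] == 50
        assert v["tag_freq"] == pytest.approx(0.25)
        assert v["best_snp_maf"] == pytest.approx(0.25)
        assert v["structure_r"] == 0.0
        # second-best chromosome carries an identical SNP -> gap 0
        assert v["chrom_gap"] == pytest.approx(0.0, abs=1e-9)

    def test_single_sig_snp_span_zero_frac_one(self):
        n = 120
        carriers = np.zeros(n, bool); carriers[:40] = True
        snps = toy_matrices(n, patterns=[carriers], mafs=[0.3])
        tags = toy_tags(snps.taxa, [carriers])
        pca = PCAResult(np.zeros((n, 3)), np.zeros(3))
        res = map_tag_gwas(0, tags, snps)
        att = extract_attributes(res, None, snps, tags, pca)
        v = dict(zip(att.names, att.values))
        assert v["sig_span_bp"] == 0.0 and v["sig_frac_best_chrom"] == 1.0

    def test_gj_agreement_attributes(self):
        snps, tags, pca = self._fixture()
        res = map_tag_gwas(0, tags, snps)
        companion = MappingResult(
            tag_index=0, sequence=tags.sequences[0], method="J", pos=res.pos,
            best_snp_index=res.best_snp_index, p_value=1e-9, neg_log10_p=9.0,
            second_best_neg_log10_p=0.0, n=40, x=40, tag_count=50, n_sig_snps=1,
            sig_snp_indices=np.array([0]), sig_neg_log10_p=np.array([9.0]),
            n_segregating_families=4, group_family_count=3, n_families=5,
        )
        att = extract_attributes(res, companion, snps, tags, pca)
        v = dict(zip(att.names, att.values))
        assert att.model_class == "GJ"
        assert v["gj_log_distance"] == 0.0
        assert v["chrom_agreement"] == 1.0
        assert v["n_seg_families"] == 4
        assert v["group_frac"] == pytest.approx(0.75)

    def test_extraction_is_pure(self, small_panel):
        mapped, _ = map_all_gwas(small_panel.tags, small_panel.snps)
        pca = structure_pca(small_panel.snps, seed=0)
        a = extract_attributes(mapped[0], None, small_panel.snps, small_panel.tags, pca)
        b = extract_attributes(mapped[0], None, small_panel.snps, small_panel.tags, pca)
        assert np.array_equal(a.values, b.values)


class TestBoxCox:
    def test_lambda_one_is_affine_shape_preserving(self):
        assert _transform(np.array([3.0]), 1.0)[0] == pytest.approx(2.0)  # v - 1

    def test_lambda_zero_is_log(self):
        v = np.array([1.0, np.e, np.e**2])
        assert np.allclose(_transform(v, 0.0), [0, 1, 2])

    def test_lognormal_recovers_lambda_near_zero(self):
        rng = np.random.default_rng(4)
        col = np.exp(rng.standard_normal(5000))
        params = boxcox_fit(col[:, None], ["a"])
        assert abs(params.lambdas[0]) < 0.15

    def test_constant_attribute_identity(self):
        mat = np.column_stack([np.full(50, 3.0), np.arange(50, dtype=float)])
        params = boxcox_fit(mat, ["c", "x"])
        assert params.lambdas[0] == 1.0

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            boxcox_fit(np.ones((10, 2)), ["a", "b"])

    def test_apply_uses_training_params_on_new_data(self):
        rng = np.random.default_rng(5)
        train = rng.gamma(2.0, size=(200, 1))
        params = boxcox_fit(train, ["a"])
        new = boxcox_apply(params, np.array([[1.5], [2.5]]))
        direct = (
            _transform(np.array([1.5, 2.5]) + params.shifts[0], params.lambdas[0])
            - params.means[0]
        ) / params.sds[0]
        assert np.allclose(new.ravel(), direct)

    def test_reduces_skewness_on_training_attributes(self, small_panel):
        mapped, _ = map_all_gwas(small_panel.tags, small_panel.snps)
        pca = structure_pca(small_panel.snps, seed=0)
        X = np.array([
            extract_attributes(r, None, small_panel.snps, small_panel.tags, pca).values
            for r in mapped
        ])
        params = boxcox_fit(X, features.ATTRIBUTE_NAMES["G"])
        T = boxcox_apply(params, X)
        for j in range(X.shape[1]):
            if X[:, j].std() == 0:
                continue
            assert abs(st.skew(T[:, j])) <= abs(st.skew(X[:, j])) + 0.1

    def test_roundtrip_through_text_lines(self):
        rng = np.random.default_rng(6)
        params = boxcox_fit(rng.gamma(2.0, size=(100, 3)), ["a", "b", "c"])
        again = features.BoxCoxParams.from_lines(params.to_lines())
        assert np.allclose(params.lambdas, again.lambdas)
        assert np.allclose(params.means, again.means)


class TestStructureErrorLink:
    def test_high_error_tags_have_larger_structure_correlation(self, small_panel):
        """Mismapped tags correlate with structure (one-sided Mann-Whitney)."""
        mapped, _ = map_all_gwas(small_panel.tags, small_panel.snps)
        pca = structure_pca(small_panel.snps, seed=0)
        truth = small_panel.truth.set_index("tag_sequence")
        errs, rs = [], []
        for r in mapped:
            row = truth.loc[r.sequence]
            if row.pav:
                continue
            g = r.pos.chromosome * 10**9 + r.pos.position
            t = row.chromosome * 10**9 + row.position
            errs.append(abs(g - t))
            presence = np.unpackbits(
                small_panel.tags.presence_packed[r.tag_index],
                count=len(small_panel.tags.taxa),
            )
            rs.append(tag_structure_correlation(presence, pca))
        errs, rs = np.asarray(errs), np.asarray(rs)
        bad = errs > np.quantile(errs, 0.75)
        stat = st.mannwhitneyu(rs[bad], rs[~bad], alternative="greater")
        assert stat.pvalue < 0.01
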