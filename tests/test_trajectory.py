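"""QC, normalization, pseudotime recovery, binning and module scoring."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tet2traj.io import ExpressionMatrix, GeneModule
from tet2traj.trajectory import (
    bin_pseudotime,
    infer_pseudotime,
    normalize_log_cpm,
    normalize_median_ratios,
    qc_filter,
    score_modules,
)


class TestQcFilter:
    def test_zero_thresholds_identity(self, tiny_counts):
        out = qc_filter(tiny_counts, 0, 0)
        assert np.array_equal(out.values, tiny_counts.values)

    def test_all_zero_cell_removed(self, tiny_counts):
        out = qc_filter(tiny_counts, 1, 0)
        assert "c2" not in out.row_ids

    def test_matches_brute_force_on_fixture(self, tiny_counts):
        # independent oracle: exhaustively apply cells-then-genes rule
        detected = tiny_counts.values > 0
        keep_cells = [i for i in range(4) if detected[i].sum() >= 2]
        keep_genes = [
            j for j in range(3) if sum(detected[i][j] for i in keep_cells) >= 2
        ]
        expected = tiny_counts.values[np.ix_(keep_cells, keep_genes)]
        out = qc_filter(tiny_counts, 2, 2)
        assert np.array_equal(out.values, expected)

    def test_all_cells_removed_is_error(self, tiny_counts):
        with pytest.raises(ValueError, match="thresholds|lower"):
            qc_filter(tiny_counts, 4, 0)


class TestNormalizeLogCpm:
    def test_single_gene_closed_form(self):
        m = ExpressionMatrix(np.array([[10_000.0]]), ["c"], ["g"], "counts")
        out = normalize_log_cpm(m)
        assert out.values[0, 0] == pytest.approx(np.log(1 + 10_000))

    def test_scale_invariance(self):
        v = np.array([[2.0, 8.0], [1.0, 3.0]])
        a = normalize_log_cpm(ExpressionMatrix(v, ["c1", "c2"], ["g1", "g2"], "counts"))
        b = normalize_log_cpm(ExpressionMatrix(3 * v, ["c1", "c2"], ["g1", "g2"], "counts"))
        assert np.allclose(a.values, b.values)

    def test_two_by_two_hand_computation(self):
        m = ExpressionMatrix(np.array([[1.0, 3.0], [2.0, 2.0]]), ["c1", "c2"], ["g1", "g2"], "counts")
        out = normalize_log_cpm(m)
        expected = np.log1p(np.array([[1 / 4, 3 / 4], [2 / 4, 2 / 4]]) * 10_000)
        assert np.allclose(out.values, expected)

    def test_zero_total_cell_rejected(self, tiny_counts):
        with pytest.raises(ValueError, match="zero total"):
            normalize_log_cpm(tiny_counts)


class TestNormalizeMedianRatios:
    def test_pure_depth_difference_removed(self):
        # cell 2 is cell 1 at double depth: identical normalized profiles
        v = np.array([[4.0, 10.0, 2.0, 7.0], [8.0, 20.0, 4.0, 14.0]])
        m = ExpressionMatrix(v, ["c1", "c2"], list("abcd"), "counts")
        out = normalize_median_ratios(m, pseudocount=0.0)
        assert np.allclose(out.values[0], out.values[1])

    def test_requires_counts(self, small_run):
        with pytest.raises(ValueError, match="counts"):
            normalize_median_ratios(small_run["normalized"])


class TestInferPseudotime:
    def test_recovers_latent_order(self, single_condition_run):
        res = single_condition_run
        rho = spearmanr(res["pseudotime"].t, res["t_true"]).statistic
        assert rho >= 0.9

    def test_reversed_root_flips_t(self, single_condition_run):
        res = single_condition_run
        norm = res["normalized"]
        genes = [g for m in res["modules"] for g in m.genes]
        root_late = next(m for m in res["modules"] if m.name == "TET2_TARGETS")
        pt_rev = infer_pseudotime(norm, genes, root_late)
        assert np.allclose(pt_rev.t, 100.0 - res["pseudotime"].t, atol=1e-6)

    def test_duplicated_cells_get_equal_t(self):
        rng = np.random.default_rng(0)
        v = np.round(rng.gamma(2.0, 3.0, size=(30, 12)))
        v = np.vstack([v, v[:1]])  # duplicate first cell
        ids = [f"c{i}" for i in range(31)]
        m = ExpressionMatrix(np.log1p(v), ids, [f"g{j}" for j in range(12)], "normalized")
        pt = infer_pseudotime(m, m.gene_ids, ["c0"])
        assert pt.t[0] == pt.t[30]

    def test_too_few_shared_genes_is_error(self, single_condition_run):
        norm = single_condition_run["normalized"]
        with pytest.raises(ValueError, match=">= 10"):
            infer_pseudotime(norm, norm.gene_ids[:5], [norm.row_ids[0]])

    def test_constant_submatrix_is_error(self):
        m = ExpressionMatrix(np.ones((20, 12)), [f"c{i}" for i in range(20)],
                             [f"g{j}" for j in range(12)], "normalized")
        with pytest.raises(ValueError, match="constant"):
            infer_pseudotime(m, m.gene_ids, ["c0"])

    def test_invariant_to_cell_permutation(self, single_condition_run):
        res = single_condition_run
        norm = res["normalized"]
        rng = np.random.default_rng(1)
        perm = rng.permutation(norm.n_rows)
        shuffled = ExpressionMatrix(
            norm.values[perm], [norm.row_ids[i] for i in perm], norm.gene_ids, "normalized"
        )
        genes = [g for m in res["modules"] for g in m.genes]
        root = next(m for m in res["modules"] if m.name == "OXPHOS")
        pt_a = infer_pseudotime(norm, genes, root)
        pt_b = infer_pseudotime(shuffled, genes, root)
        t_by_cell = dict(zip(pt_b.cell_ids, pt_b.t))
        assert np.allclose(pt_a.t, [t_by_cell[c] for c in pt_a.cell_ids], atol=1e-9)


class TestBinPseudotime:
    def _pt(self, n):
        from tet2traj.trajectory import PseudotimeAssignment

        t = np.linspace(0, 100, n)
        return PseudotimeAssignment([f"c{i:04d}" for i in range(n)], t, 0.0)

    def test_exact_division(self):
        pt = bin_pseudotime(self._pt(200), 100)
        counts = np.bincount(pt.bin)[1:]
        assert (counts == 2).all()

    def test_remainder_distribution(self):
        pt = bin_pseudotime(self._pt(201), 100)
        counts = np.bincount(pt.bin)[1:]
        assert sorted(counts)[-1] == 3
        assert (np.sort(counts)[:-1] == 2).all()

    def test_bin_increases_with_t(self):
        pt = bin_pseudotime(self._pt(250), 100)
        order = np.argsort(pt.t)
        assert (np.diff(pt.bin[order]) >= 0).all()

    def test_too_few_cells_or_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_pseudotime(self._pt(50), 100)
        with pytest.raises(ValueError):
            bin_pseudotime(self._pt(50), 1)


class TestScoreModules:
    def test_singleton_module_equals_gene_zscore(self, single_condition_run):
        res = single_condition_run
        norm = res["normalized"]
        gene = res["modules"][0].genes[0]
        single = GeneModule("ONE", (gene,))
        _, scores = score_modules(norm, [single], res["pseudotime"])
        col = norm.values[:, norm.gene_ids.index(gene)]
        z = (col - col.mean()) / col.std()
        assert np.allclose(scores["ONE"].to_numpy(), z)

    def test_scores_center_at_zero(self, small_run):
        scores = small_run["cell_scores"]
        assert (scores.mean(axis=0).abs() < 1e-8).all()

    def test_tet2_bin_curve_rises(self, single_condition_run):
        prof = single_condition_run["profile"]
        rho = spearmanr(prof.bins, prof.module_scores["TET2_TARGETS"]).statistic
        assert rho > 0.8

    def test_unshared_module_names_the_module(self, single_condition_run):
        res = single_condition_run
        bad = GeneModule("GHOST", ("NOPE1", "NOPE2"))
        with pytest.raises(ValueError, match="GHOST"):
            score_modules(res["normalized"], [bad], res["pseudotime"])

    def test_bin_curves_track_generative_sigmoids(self, single_condition_run):
        # bin-mean scores should match the noiseless activation curves up to
        # an affine transform: Pearson r against the generative sigmoid
        from tet2traj.simulate import default_module_params, module_mean

        res = single_condition_run
        prof = res["profile"]
        cfg_params = {p.module_name: p for p in default_module_params()}
        # bin-mean true t for the abscissa
        pt = res["pseudotime"]
        t_true = res["t_true"]
        for name, p in cfg_params.items():
            bin_true_t = np.array([t_true[pt.bin == b].mean() for b in prof.bins])
            expected = module_mean(bin_true_t, p)
            r = np.corrcoef(expected, prof.module_scores[name])[0, 1]
            assert abs(r) >= 0.97
            assert np.sign(r) > 0
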