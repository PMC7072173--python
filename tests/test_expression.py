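"""Diploid-referenced Z-scores, calls, rates and CNA/expression concordance."""

import numpy as np
import pandas as pd
import pytest

from snocna.expression import (classify_expression, cna_expression_concordance,
                               compute_z, expression_rates, top_k_upregulated)
from snocna.io_cbio import CnaMatrix, ExprMatrix

from conftest import make_cohort, make_couples, random_codes
from oracles import oracle_expression_rates, oracle_zscores


def matrices(expr_rows, cna_rows, genes=None):
    expr_rows = np.asarray(expr_rows, dtype=float)
    n, m = expr_rows.shape
    genes = genes or [f"G{i}" for i in range(n)]
    samples = [f"s{j}" for j in range(m)]
    idx = pd.Index(genes, name="gene_id")
    return (ExprMatrix(values=pd.DataFrame(expr_rows, index=idx, columns=samples)),
            CnaMatrix(codes=pd.DataFrame(np.asarray(cna_rows, dtype=float),
                                         index=idx, columns=samples)))


class TestComputeZ:
    def test_reference_arithmetic_and_strict_threshold(self):
        """Reference {1,2,3} gives mu=2, sd=1; value 4 scores z=2 -> normal."""
        expr, cna = matrices([[1, 2, 3, 4]], [[0, 0, 0, 2]])
        zm = compute_z(expr, cna)
        np.testing.assert_allclose(zm.z.to_numpy(), [[-1, 0, 1, 2]], atol=1e-12)
        calls = classify_expression(zm)
        assert calls.iloc[0].tolist() == ["normal"] * 4

    def test_constant_reference_is_undefined(self):
        expr, cna = matrices([[5, 5, 5, 9]], [[0, 0, 0, 2]])
        zm = compute_z(expr, cna)
        assert zm.z.isna().all().all()
        assert list(zm.undefined_genes) == ["G0"]

    def test_small_reference_is_undefined(self):
        expr, cna = matrices([[1, 2, 9]], [[0, 0, 2]])
        assert compute_z(expr, cna, min_ref=3).z.isna().all().all()

    def test_no_shared_samples_is_hard_error(self):
        expr, cna = matrices([[1, 2, 3]], [[0, 0, 0]])
        cna.codes.columns = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="no samples"):
            compute_z(expr, cna)

    def test_reference_standardization_invariant(self, rng):
        """Diploid reference z-values have mean 0 and sd 1 per gene."""
        n, m = 12, 60
        codes = random_codes(rng, n, m)
        expr_vals = np.exp(rng.normal(2, 1, size=(n, m)))
        expr, cna = matrices(expr_vals, codes)
        zm = compute_z(expr, cna)
        arr = zm.z.to_numpy()
        ref = codes == 0
        for i in range(n):
            if np.isnan(arr[i]).all():
                continue
            vals = arr[i][ref[i]]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=1) - 1) < 1e-9

    def test_matches_per_gene_loop_oracle(self, rng):
        n, m = 15, 25
        codes = random_codes(rng, n, m, p_missing=0.1)
        expr_vals = np.exp(rng.normal(0, 1.5, size=(n, m)))
        expr, cna = matrices(expr_vals, codes)
        zm = compute_z(expr, cna)
        expected = oracle_zscores(expr_vals.tolist(), codes.tolist())
        for i in range(n):
            for j in range(m):
                e = expected[i][j]
                got = zm.z.iat[i, j]
                if e is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(e, abs=1e-9)

    def test_affine_rescaling_leaves_calls_unchanged(self, rng):
        n, m = 6, 40
        codes = random_codes(rng, n, m)
        expr_vals = np.exp(rng.normal(1, 1, size=(n, m)))
        expr, cna = matrices(expr_vals, codes)
        calls = classify_expression(compute_z(expr, cna))
        expr2, _ = matrices(3.7 * expr_vals + 11.0, codes)
        calls2 = classify_expression(compute_z(expr2, cna))
        pd.testing.assert_frame_equal(calls, calls2)


class TestClassifyExpression:
    @pytest.mark.parametrize("z,call", [
        (2.0001, "up"), (-2.0001, "down"), (-2.0, "normal"), (2.0, "normal"),
        (0.0, "normal"), (float("nan"), "undefined"),
    ])
    def test_threshold_semantics(self, z, call):
        expr, cna = matrices([[1, 2, 3]], [[0, 0, 0]])
        zm = compute_z(expr, cna)
        zm.z.iloc[0, :] = z
        assert classify_expression(zm).iat[0, 0] == call


def _call_setup(rng, n_couples=5, n_samples=20):
    couples = make_couples(n_couples)
    sno_codes = random_codes(rng, n_couples, n_samples)
    host_codes = random_codes(rng, n_couples, n_samples)
    expr_vals = np.exp(rng.normal(2, 1, size=(2 * n_couples, n_samples)))
    cohort, aligned = make_cohort(sno_codes, host_codes, couples=couples,
                                  expr=expr_vals)
    zm = compute_z(cohort.expr, cohort.cna)
    calls = classify_expression(zm)
    return cohort, aligned, calls


class TestExpressionRates:
    def test_all_normal_cohort_has_zero_rates(self):
        couples = make_couples(1)
        cohort, aligned = make_cohort([[0, 0, 0, 0]], [[0, 0, 0, 0]],
                                      couples=couples,
                                      expr=[[1, 2, 3, 2], [1, 2, 3, 2]])
        calls = classify_expression(compute_z(cohort.expr, cohort.cna))
        rates = expression_rates(calls, aligned, cohort)
        assert (rates["rate_per_sample"] == 0).all()

    def test_direct_ratio_host_up(self):
        couples = make_couples(1)
        cohort, aligned = make_cohort([[0, 0]], [[0, 0]], couples=couples)
        calls = pd.DataFrame([["normal", "normal"], ["up", "normal"]],
                             index=[couples[0].snorna_id, couples[0].host_id],
                             columns=cohort.sample_ids)
        rates = expression_rates(calls, aligned, cohort)
        host_up = rates.query("member == 'host' and direction == 'up'")
        assert host_up["rate_per_sample"].iloc[0] == pytest.approx(0.5)

    def test_matches_nested_loop_oracle(self, rng):
        cohort, aligned, calls = _call_setup(rng)
        rates = expression_rates(calls, aligned, cohort)
        sno_rows = [calls.loc[c.snorna_id].tolist() for c in aligned.couples]
        host_rows = [calls.loc[c.host_id].tolist() for c in aligned.couples]
        expected = oracle_expression_rates(sno_rows, host_rows, cohort.n_samples)
        for _, row in rates.iterrows():
            assert row["rate_per_sample"] == pytest.approx(
                expected[(row["member"], row["direction"])])

    def test_empty_couple_set_is_error(self, rng):
        cohort, aligned, calls = _call_setup(rng)
        aligned.couples = []
        with pytest.raises(ValueError):
            expression_rates(calls, aligned, cohort)


class TestTopKUpregulated:
    def test_host_only_flag_and_fraction(self):
        couples = make_couples(1)
        cohort, aligned = make_cohort(np.zeros((1, 10)), np.zeros((1, 10)),
                                      couples=couples)
        calls = pd.DataFrame(
            [["normal"] * 10,
             ["up", "up", "up"] + ["normal"] * 7],
            index=[couples[0].snorna_id, couples[0].host_id],
            columns=cohort.sample_ids)
        top = top_k_upregulated(calls, aligned, cohort)
        assert top["upregulated_fraction"].iloc[0] == pytest.approx(0.3)
        assert top["member"].iloc[0] == "host_only"

    def test_both_members_up_counts_once(self):
        couples = make_couples(1)
        cohort, aligned = make_cohort(np.zeros((1, 2)), np.zeros((1, 2)),
                                      couples=couples)
        calls = pd.DataFrame([["up", "normal"], ["up", "normal"]],
                             index=[couples[0].snorna_id, couples[0].host_id],
                             columns=cohort.sample_ids)
        top = top_k_upregulated(calls, aligned, cohort)
        assert top["n_upregulated_samples"].iloc[0] == 1
        assert top["member"].iloc[0] == "both"

    def test_matches_sort_oracle(self, rng):
        from oracles import oracle_top_k
        cohort, aligned, calls = _call_setup(rng, n_couples=12, n_samples=30)
        top = top_k_upregulated(calls, aligned, cohort, k=6)
        items = []
        for c in aligned.couples:
            sno = calls.loc[c.snorna_id]
            host = calls.loc[c.host_id]
            n_eval = sum(1 for a, b in zip(sno, host)
                         if a != "undefined" or b != "undefined")
            n_up = sum(1 for a, b in zip(sno, host) if a == "up" or b == "up")
            items.append((n_up / n_eval if n_eval else 0.0, c.label, c.snorna_id))
        expected = oracle_top_k(items, 6)
        got = list(zip(top["upregulated_fraction"], top["label"], top["snorna_id"]))
        for g, e in zip(got, expected):
            assert g[0] == pytest.approx(e[0])
            assert g[1:] == e[1:]


class TestConcordance:
    def test_no_amplified_cells_is_undefined_fraction(self):
        couples = make_couples(1)
        cohort, aligned = make_cohort(np.zeros((1, 4)), np.zeros((1, 4)),
                                      couples=couples,
                                      expr=np.ones((2, 4)) * [[1, 2, 3, 9]])
        calls = classify_expression(compute_z(cohort.expr, cohort.cna))
        conc = cna_expression_concordance(calls, aligned, cohort)
        assert np.isnan(conc["per_couple"]["frac_amplified_also_up"].iloc[0])

    def test_overlap_matches_set_intersection(self, rng):
        from snocna.coalteration import summarize_cohort, top_k_couples
        cohort, aligned, calls = _call_setup(rng, n_couples=15, n_samples=25)
        cna_top = top_k_couples(summarize_cohort(cohort, aligned), k=5)
        expr_top = top_k_upregulated(calls, aligned, cohort, k=5)
        conc = cna_expression_concordance(calls, aligned, cohort, k=5,
                                          cna_top=cna_top, expr_top=expr_top)
        expected = set(cna_top["label"]) & set(expr_top["label"])
        assert conc["topk_overlap"]["n_overlap"] == len(expected)
        assert set(conc["topk_overlap"]["overlap_labels"]) == expected

    def test_dosage_coupled_cohort_amplified_cells_called_up(self):
        """Strong dosage effect with low noise drives amplified cells to up."""
        from snocna.simulate import GeneratorParams, generate
        from snocna.pairing import align_couples
        params = GeneratorParams(n_couples=40, cohorts={"SIM": 300},
                                 p_alt=0.2, p_amp=1.0, f_amp=4.0, noise_sd=0.1,
                                 frac_never=0.0, frac_all=1.0, rng_seed=7)
        result = generate(params)
        cohort = result.cohorts[0]
        aligned = align_couples(result.couples, cohort)
        calls = classify_expression(compute_z(cohort.expr, cohort.cna))
        conc = cna_expression_concordance(calls, aligned, cohort)
        frac = conc["per_couple"]["frac_amplified_also_up"].dropna()
        assert len(frac) > 10
        assert frac.mean() > 0.95
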