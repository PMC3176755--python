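"""Summarization: convolution background, quantile step, median polish,
RMA and the model-based index, each against an independent oracle."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import panpflow as pf
from panpflow.containers import IntensityMatrix
from panpflow.summarize import (
    estimate_background_params,
    median_polish_blocks,
    normexp_signal,
)

from .conftest import trivial_annotation


def quadrature_conditional_mean(o, mu, sigma, alpha):
    """E[S | O=o] by numerical integration of the posterior density."""

    def dens(s):
        return alpha * np.exp(-alpha * s) * stats.norm.pdf(o - s, mu, sigma)

    hi = o + 20 * sigma + 20 / alpha
    z, _ = integrate.quad(dens, 0, hi, limit=400)
    num, _ = integrate.quad(lambda s: s * dens(s), 0, hi, limit=400)
    return num / z


class TestBackgroundCorrect:
    def test_monotone_in_input(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.gamma(2, 50, 200)) + 1
        out = normexp_signal(x, mu=40.0, sigma=10.0, alpha=0.01)
        assert np.all(np.diff(out) > 0)
        assert np.all(out > 0)

    @pytest.mark.parametrize("o", [20.0, 45.0, 80.0, 300.0])
    def test_matches_quadrature_oracle(self, o):
        mu, sigma, alpha = 40.0, 12.0, 0.008
        got = float(normexp_signal(np.array([o]), mu, sigma, alpha)[0])
        want = quadrature_conditional_mean(o, mu, sigma, alpha)
        assert got == pytest.approx(want, rel=1e-6)

    def test_small_sigma_limit(self):
        # with sigma -> 0 and o >> mu the correction tends to o - mu
        got = float(normexp_signal(np.array([500.0]), 40.0, 1e-4, 1e-6)[0])
        assert got == pytest.approx(500.0 - 40.0, abs=1e-3)

    def test_degenerate_array_errors(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_background_params(np.full(50, 7.0))

    def test_injected_params_bypass_estimation(self, small_world):
        raw = small_world["raw"]
        params = {a: (40.0, 10.0, 0.01) for a in raw.array_ids}
        out = pf.background_correct(raw, params=params)
        expected = normexp_signal(raw.values[:, 0], 40.0, 10.0, 0.01)
        np.testing.assert_allclose(out.values[:, 0], expected)


class TestQuantileNormalize:
    def test_hand_computed_case(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]])
        out = pf.quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 6.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.5, 6.5])

    def test_single_array_unchanged(self):
        m = np.array([[3.0], [1.0], [2.0]])
        np.testing.assert_array_equal(pf.quantile_normalize(m), m)

    def test_identical_columns_fixed_point(self):
        col = np.array([4.0, 1.0, 9.0, 2.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(pf.quantile_normalize(m), m)

    def test_ties_share_mean_of_rank_means(self):
        m = np.array([[1.0, 5.0], [1.0, 2.0], [4.0, 7.0]])
        out = pf.quantile_normalize(m)
        # column 0 has a tie at ranks 0,1: both get the mean of ref[0], ref[1]
        assert out[0, 0] == out[1, 0]
        np.testing.assert_allclose(out.sum(axis=0), out.sum(axis=0)[0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.gamma(2, 10, size=(12, 4))
        once = pf.quantile_normalize(m)
        np.testing.assert_allclose(pf.quantile_normalize(once), once, atol=1e-12)

    def test_column_sorted_values_equalized(self):
        rng = np.random.default_rng(3)
        m = rng.normal(100, 20, size=(30, 5))
        out = pf.quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)


def oracle_median_polish(block, tol=0.01, max_iter=10):
    """Independently coded sweep implementation using statistics.median."""
    rows, cols = len(block), len(block[0])
    resid = [list(r) for r in block]
    overall, row_eff, col_eff = 0.0, [0.0] * rows, [0.0] * cols
    for _ in range(max_iter):
        deltas = []
        for i in range(rows):
            m = statistics.median(resid[i])
            deltas.append(abs(m))
            row_eff[i] += m
            for j in range(cols):
                resid[i][j] -= m
        m = statistics.median(row_eff)
        overall += m
        row_eff = [r - m for r in row_eff]
        for j in range(cols):
            m = statistics.median([resid[i][j] for i in range(rows)])
            deltas.append(abs(m))
            col_eff[j] += m
            for i in range(rows):
                resid[i][j] -= m
        m = statistics.median(col_eff)
        overall += m
        col_eff = [c - m for c in col_eff]
        if max(deltas) < tol:
            break
    return overall, row_eff, col_eff, resid


class TestMedianPolish:
    def test_additive_matrix_zero_residuals(self):
        r = np.array([1.0, 2.0, 5.0])
        c = np.array([0.0, 3.0, -1.0, 2.0])
        block = r[:, None] + c[None, :]
        overall, re, ce, resid = pf.median_polish(block)
        np.testing.assert_allclose(resid, 0, atol=1e-12)
        np.testing.assert_allclose(overall + re[:, None] + ce[None, :], block, atol=1e-12)

    def test_outlier_block_matches_independent_oracle(self):
        block = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [1.5, 9.0, 3.5]])
        got = pf.median_polish(block, tol=1e-9, max_iter=50)
        want = oracle_median_polish(block.tolist(), tol=1e-9, max_iter=50)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        np.testing.assert_allclose(got[1], want[1], atol=1e-9)
        np.testing.assert_allclose(got[2], want[2], atol=1e-9)

    def test_single_probe_block(self):
        block = np.array([[4.0, 6.0, 5.0]])
        overall, re, ce, _ = pf.median_polish(block)
        np.testing.assert_allclose(overall + ce, block[0])
        assert re[0] == pytest.approx(0.0)

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            pf.median_polish(np.array([[1.0, np.nan]]))

    def test_vectorized_blocks_match_scalar_path(self):
        rng = np.random.default_rng(5)
        blocks = rng.normal(8, 1, size=(20, 11, 4))
        vec = median_polish_blocks(blocks)
        for s in range(20):
            overall, _re, ce, _ = pf.median_polish(blocks[s])
            np.testing.assert_allclose(vec[s], overall + ce, atol=1e-12)


class TestRma:
    def test_output_shape_and_tag(self, atlas):
        expr = pf.rma(atlas["raw"], atlas["annotation"])
        n_sets = len(atlas["annotation"].probeset_to_probes)
        assert expr.values.shape == (n_sets, len(atlas["raw"].array_ids))
        assert expr.method == "rma"

    def test_planted_effect_recovered(self):
        """A +4 log2 effect on a moderately expressed gene survives RMA.

        Conditions under which RMA preserves effects: the gene's signal
        dominates the optical background (so background subtraction is a
        small correction) and its intensities fall in a dense region of the
        across-array distribution (so quantile normalization maps its ranks
        faithfully). Dim genes inflate after background subtraction and
        lone extreme-tail genes are attenuated by the quantile step — both
        are properties of the method, exercised elsewhere.
        """
        import copy

        cfg = pf.SimulationConfig(
            n_genes=120, probes_per_set=11, n_tissues=6, replicates_per_tissue=4,
            n_negative_probes=40, planted_enriched=(("G00010", "tissue00", 4.0),),
            expressed_fraction=1.0, seed=202,
        )
        _, _, _, truth = pf.generate_sequences(cfg)
        truth = copy.deepcopy(truth)
        truth.gene_levels["G00010"] = 3.5  # mid-distribution expression
        raw = pf.simulate_intensities(cfg, truth)
        expr = pf.rma(raw, trivial_annotation(truth))
        frame = expr.to_frame()
        groups = expr.groups()
        row = frame.loc["G00010_at"]
        target = row[groups["tissue00"]].mean()
        rest = row[[a for tt in groups for a in groups[tt] if tt != "tissue00"]].mean()
        assert target - rest == pytest.approx(4.0, abs=0.3)

    def test_probe_row_permutation_invariance(self, small_world, small_annotation):
        raw = small_world["raw"]
        ann = small_annotation["annotation"]
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(raw.probe_ids))
        shuffled = IntensityMatrix(
            values=raw.values[perm, :],
            probe_ids=[raw.probe_ids[i] for i in perm],
            array_ids=list(raw.array_ids),
            array_meta=dict(raw.array_meta),
        )
        a = pf.rma(raw, ann)
        b = pf.rma(shuffled, ann)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_missing_probe_errors(self, small_world, small_annotation):
        raw = small_world["raw"]
        ann = small_annotation["annotation"]
        dropped = sorted(ann.used_probes)[0]
        keep = [i for i, p in enumerate(raw.probe_ids) if p != dropped]
        sub = IntensityMatrix(
            values=raw.values[keep, :],
            probe_ids=[raw.probe_ids[i] for i in keep],
            array_ids=list(raw.array_ids),
        )
        with pytest.raises(ValueError, match="absent"):
            pf.rma(sub, ann)


class TestMbei:
    def test_noiseless_multiplicative_model_recovered(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0.5, 2.0, 7)
        phi *= np.sqrt(7 / np.sum(phi**2))
        theta = rng.uniform(50, 500, 5)
        block = phi[:, None] * theta[None, :]
        from panpflow.summarize import _fit_mbei_block

        got = _fit_mbei_block(block)
        np.testing.assert_allclose(got, theta, rtol=1e-8)

    def test_theta_order_preserved_under_noise(self, atlas):
        expr = pf.mbei(atlas["raw"], atlas["annotation"])
        frame = expr.to_frame()
        truth = atlas["truth"]
        groups = expr.groups()
        # per gene, tissue means must rank like the planted expression state
        rho = []
        for ps in frame.index[:40]:
            g = atlas["annotation"].probeset_to_gene[ps]
            means = np.array([frame.loc[ps, groups[t]].mean() for t in groups])
            state = np.array([float(truth.expressed[g][t]) for t in groups])
            if state.std() == 0:
                continue
            rho.append(stats.spearmanr(means, state).statistic)
        assert np.mean([r > 0 for r in rho]) >= 0.95

    def test_single_probe_probeset_proportional(self):
        rng = np.random.default_rng(2)
        from panpflow.summarize import _fit_mbei_block

        row = rng.uniform(10, 100, size=(1, 6))
        got = _fit_mbei_block(row)
        ratio = got / row[0]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_needs_two_arrays(self, small_world, small_annotation):
        raw = small_world["raw"]
        one = IntensityMatrix(
            values=raw.values[:, :1], probe_ids=list(raw.probe_ids), array_ids=raw.array_ids[:1]
        )
        with pytest.raises(ValueError, match="two arrays"):
            pf.mbei(one, small_annotation["annotation"])


def test_both_methods_recover_planted_contrasts():
    """Tissue contrasts from rma and mbei correlate with planted effects.

    Ubiquitously expressed genes give a true target-vs-rest contrast equal
    to the planted effect (zero for nulls), so the across-gene correlation
    isolates how faithfully each summarization transmits fold changes."""
    planted = tuple(
        (f"G{i:05d}", "tissue00", float(e)) for i, e in zip(range(8), np.linspace(1, 4, 8))
    )
    cfg = pf.SimulationConfig(
        n_genes=120, probes_per_set=11, n_tissues=6, replicates_per_tissue=4,
        n_negative_probes=40, planted_enriched=planted, expressed_fraction=1.0, seed=303,
    )
    _, _, _, truth = pf.generate_sequences(cfg)
    ann = trivial_annotation(truth)
    raw = pf.simulate_intensities(cfg, truth)
    effects = {f"{g}_at": e for g, _t, e in planted}
    for method in (pf.rma, pf.mbei):
        expr = method(raw, ann)
        frame = expr.to_frame()
        groups = expr.groups()
        rest = [a for t in groups for a in groups[t] if t != "tissue00"]
        est = [
            float(frame.loc[ps, groups["tissue00"]].mean() - frame.loc[ps, rest].mean())
            for ps in frame.index
        ]
        want = [effects.get(ps, 0.0) for ps in frame.index]
        assert np.corrcoef(est, want)[0, 1] >= 0.95
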