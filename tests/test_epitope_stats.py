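"""Layer-coverage statistics, rank-sum tests, per-protein correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hullprot.epitope_stats import (
    average_layer_stats,
    k0_distribution,
    layer_stats,
    per_protein_pcc,
    rank_sum_test,
    read_s1_table,
    s1_summary,
)
from hullprot.hull_peeling import HullDecomposition
from hullprot.structure_model import EpitopeAnnotation

from .oracles import exhaustive_ranksum_p


def make_decomp(levels, epitope_flags):
    """Residue-level decomposition from parallel level/label lists."""
    level_map = {("A", i + 1, ""): int(l) for i, l in enumerate(levels)}
    labels = EpitopeAnnotation(
        {("A", i + 1, ""): bool(e) for i, e in enumerate(epitope_flags)}
    )
    decomp = HullDecomposition(
        atom_level=np.array(sorted(levels)),
        residue_level=level_map,
        n_levels=max(levels),
        X_size=len(levels),
    )
    return decomp, labels


class TestLayerStats:
    def test_worked_example_20_10_10(self):
        # 10 epitopes / 200 exposed; layer 1 holds 2 epitopes among 20 residues
        levels = [1] * 20 + [2] * 180
        flags = [True] * 2 + [False] * 18 + [True] * 8 + [False] * 172
        decomp, labels = make_decomp(levels, flags)
        st = layer_stats(decomp, labels)
        assert st.crepi[0] == pytest.approx(0.20)
        assert st.crexp[0] == pytest.approx(0.10)
        assert st.prop[0] == pytest.approx(0.10)

    def test_single_layer_degenerate(self):
        decomp, labels = make_decomp([1] * 10, [True] * 3 + [False] * 7)
        st = layer_stats(decomp, labels)
        assert st.crepi[0] == 1.0 and st.crexp[0] == 1.0
        assert st.prop[0] == pytest.approx(0.3)

    def test_matches_direct_counting_on_random_labelling(self, shell_cloud, rng):
        from hullprot.hull_peeling import convex_hull_peel

        levels = convex_hull_peel(shell_cloud.points)
        flags = shell_cloud.epitope
        decomp, labels = make_decomp(levels.tolist(), flags.tolist())
        st = layer_stats(decomp, labels)
        for k in range(1, st.n_levels + 1):
            in_k = levels == k
            assert st.crepi[k - 1] == pytest.approx(flags[in_k].sum() / flags.sum())
            assert st.crexp[k - 1] == pytest.approx(in_k.sum() / len(levels))
            assert st.prop[k - 1] == pytest.approx(flags[in_k].mean())

    def test_cumulate_is_running_sum_and_reaches_one(self, shell_cloud):
        from hullprot.hull_peeling import convex_hull_peel

        levels = convex_hull_peel(shell_cloud.points)
        decomp, labels = make_decomp(levels.tolist(), shell_cloud.epitope.tolist())
        st = layer_stats(decomp, labels)
        np.testing.assert_allclose(st.crepi_cum, np.cumsum(st.crepi))
        np.testing.assert_allclose(st.crexp_cum, np.cumsum(st.crexp))
        assert st.crepi_cum[-1] == pytest.approx(1.0)
        assert st.crexp_cum[-1] == pytest.approx(1.0)
        assert st.crepi.sum() == pytest.approx(1.0)
        assert st.crexp.sum() == pytest.approx(1.0)
        # non-decreasing cumulates
        assert np.all(np.diff(st.crepi_cum) >= -1e-12)
        assert np.all(np.diff(st.crexp_cum) >= -1e-12)

    def test_prop_cum_is_weighted_average(self):
        decomp, labels = make_decomp(
            [1, 1, 1, 1, 2, 2], [True, False, False, False, True, True]
        )
        st = layer_stats(decomp, labels)
        assert min(st.prop[:2]) - 1e-12 <= st.prop_cum[1] <= max(st.prop[:2]) + 1e-12
        assert st.prop_cum[1] == pytest.approx(3 / 6)

    def test_cross_protein_average_is_unweighted(self):
        d1, l1 = make_decomp([1] * 10, [True] * 5 + [False] * 5)
        d2, l2 = make_decomp([1] * 1000, [True] * 100 + [False] * 900)
        avg = average_layer_stats([layer_stats(d1, l1), layer_stats(d2, l2)], k_max=2)
        assert avg.loc[1, "prop"] == pytest.approx((0.5 + 0.1) / 2)
        assert avg.loc[2, "crexp"] == 0.0  # beyond both proteins' layers

    def test_cumulate_average_clamps_beyond_n_levels(self):
        d1, l1 = make_decomp([1, 2], [True, False])
        avg = average_layer_stats([layer_stats(d1, l1)], k_max=5, cumulate=True)
        assert avg.loc[5, "crepi"] == pytest.approx(1.0)
        assert avg.loc[5, "crexp"] == pytest.approx(1.0)


class TestK0Distribution:
    def test_histogram_and_cumulative(self):
        hist, cum = k0_distribution([1, 2, 2, 3])
        assert hist == {1: 1, 2: 2, 3: 1}
        assert cum[2] == pytest.approx(0.75)
        assert cum[3] == pytest.approx(1.0)

    def test_order_invariance(self):
        a = k0_distribution([3, 1, 2, 2])
        b = k0_distribution([2, 2, 3, 1])
        assert a == b

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            k0_distribution([])


class TestRankSumTest:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            res = rank_sum_test([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    def test_separated_samples_one_sided_exact(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], alternative="less")
        assert res.p_value == pytest.approx(0.05)  # 1/20 arrangements

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration_small_n(self, seed, alternative):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 40, size=int(rng.integers(3, 8))).tolist()
        y = rng.integers(0, 40, size=int(rng.integers(3, 8))).tolist()
        if len(set(x + y)) < len(x + y):
            x = [float(v) + 0.01 * i for i, v in enumerate(x)]  # break ties
            y = [float(v) + 0.01 * (i + len(x)) for i, v in enumerate(y)]
        res = rank_sum_test(x, y, alternative=alternative)
        assert res.p_value == pytest.approx(
            exhaustive_ranksum_p(list(map(float, x)), list(map(float, y)), alternative)
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_large_separated_samples_tiny_p(self, rng):
        x = rng.normal(0.0, 1.0, 300)
        y = rng.normal(3.0, 1.0, 300)
        res = rank_sum_test(x, y, alternative="less")
        assert res.p_value < 1e-16


class TestPerProteinPcc:
    def _grouping(self, n, n_proteins):
        keys = [("A", i + 1, "") for i in range(n)]
        grouping = {k: f"P{i % n_proteins}" for i, k in enumerate(keys)}
        return keys, grouping

    def test_self_correlation_is_one(self, rng):
        keys, grouping = self._grouping(60, 3)
        rsa = {k: float(v) for k, v in zip(keys, rng.uniform(0, 100, 60))}
        mean, sd, n = per_protein_pcc(rsa, rsa, grouping)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert n == 3

    def test_sign_flip(self, rng):
        keys, grouping = self._grouping(60, 3)
        rsa = {k: float(v) for k, v in zip(keys, rng.uniform(0, 100, 60))}
        neg = {k: -v for k, v in rsa.items()}
        mean, _, _ = per_protein_pcc(neg, rsa, grouping)
        assert mean == pytest.approx(-1.0)

    def test_noisy_linear_feature_matches_direct_formula(self, rng):
        keys, grouping = self._grouping(400, 20)
        rsa = {k: float(v) for k, v in zip(keys, rng.uniform(0, 100, 400))}
        feature = {k: 0.8 * v + rng.normal(0, 5.0) for k, v in rsa.items()}
        mean, _, n = per_protein_pcc(feature, rsa, grouping)
        # independent recomputation from raw covariance sums
        pccs = []
        for pid in {grouping[k] for k in keys}:
            f = [feature[k] for k in keys if grouping[k] == pid]
            r = [rsa[k] for k in keys if grouping[k] == pid]
            m = len(f)
            sf, sr = sum(f), sum(r)
            cov = sum(a * b for a, b in zip(f, r)) - sf * sr / m
            vf = sum(a * a for a in f) - sf * sf / m
            vr = sum(b * b for b in r) - sr * sr / m
            pccs.append(cov / math.sqrt(vf * vr))
        assert n == 20
        assert mean == pytest.approx(sum(pccs) / len(pccs), abs=0.01)

    def test_zero_variance_protein_skipped(self):
        keys, grouping = self._grouping(6, 2)
        rsa = {k: float(i) for i, k in enumerate(keys)}
        feature = {k: (5.0 if grouping[k] == "P0" else float(i))
                   for i, k in enumerate(keys)}
        _, _, n = per_protein_pcc(feature, rsa, grouping)
        assert n == 1


class TestS1Tables:
    def _synthetic_table(self, rng, n_epi=40, n_non=200):
        """Synthetic stand-in for a per-residue RSA/depth table."""
        return pd.DataFrame(
            {
                "Label": ["Epitope"] * n_epi + ["Non-epitope"] * n_non,
                "RSA": np.concatenate(
                    [rng.uniform(20, 90, n_epi), rng.uniform(0.1, 70, n_non)]
                ),
                "Chakravarty Depth": np.concatenate(
                    [rng.uniform(3, 6, n_epi), rng.uniform(3.5, 9, n_non)]
                ),
                "DPX": np.concatenate(
                    [rng.uniform(0, 1, n_epi), rng.uniform(0, 2, n_non)]
                ),
            }
        )

    def test_reader_normalises_columns_csv(self, tmp_path, rng):
        df = self._synthetic_table(rng)
        f = tmp_path / "table.csv"
        df.to_csv(f, index=False)
        out = read_s1_table(f)
        assert {"label", "rsa", "chakravarty", "dpx", "epitope"} <= set(out.columns)
        assert out["epitope"].sum() == 40

    def test_reader_handles_xlsx(self, tmp_path, rng):
        pytest.importorskip("openpyxl")
        df = self._synthetic_table(rng)
        f = tmp_path / "table.xlsx"
        df.to_excel(f, index=False)
        out = read_s1_table(f)
        assert out["epitope"].sum() == 40

    def test_summary_statistics(self, tmp_path, rng):
        df = self._synthetic_table(rng)
        f = tmp_path / "table.csv"
        df.to_csv(f, index=False)
        out = read_s1_table(f)
        summary = s1_summary(out)
        assert summary["n_epitopes"] == 40
        assert summary["n_non_epitopes"] == 200
        epi = df[df["Label"] == "Epitope"]
        assert summary["rsa_epitope_mean"] == pytest.approx(epi["RSA"].mean())
        assert summary["max_epitope_chakravarty"] == pytest.approx(
            epi["Chakravarty Depth"].max()
        )
        assert summary["chakravarty_p_value"] < 0.05
        assert summary["rsa_alternative"] == "greater"
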