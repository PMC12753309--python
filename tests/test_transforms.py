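import numpy as np
import pandas as pd
import pytest

import sedabench as sb
from sedabench.transforms import (css_factors, gmpr_size_factors,
                                  median_of_ratios_factors, tmm_norm_factors)

import _oracles as oracle


def _tm(counts, method, **kwargs):
    return sb.transform(counts, sb.TransformOptions(method=method, **kwargs))


class TestHandValues:
    def test_prop_row(self):
        counts = pd.DataFrame([[2, 3, 5]], index=["s"], columns=list("abc"))
        assert np.allclose(_tm(counts, "prop").data.to_numpy(), [[0.2, 0.3, 0.5]])

    def test_hellinger_row(self):
        counts = pd.DataFrame([[1, 3]], index=["s"], columns=list("ab"))
        assert np.allclose(_tm(counts, "hellinger").data.to_numpy(),
                           [[0.5, 0.8660254]], atol=1e-6)

    def test_clr_no_pseudocount_needed(self):
        counts = pd.DataFrame([[1, 10, 100]], index=["s"], columns=list("abc"))
        out = _tm(counts, "clr", clr_pseudocount=0).data.to_numpy()
        assert np.allclose(out, [[-2.3025851, 0.0, 2.3025851]], atol=1e-6)


class TestOracleEquivalence:
    """Every closed-form transform matches an independent brute-force
    implementation on a random sparse matrix."""

    def test_prop(self, small_counts):
        assert np.allclose(_tm(small_counts, "prop").data.to_numpy(),
                           oracle.prop_rows(small_counts.to_numpy()), atol=1e-8)

    def test_hellinger(self, small_counts):
        assert np.allclose(_tm(small_counts, "hellinger").data.to_numpy(),
                           oracle.hellinger_rows(small_counts.to_numpy()), atol=1e-8)

    def test_chi_square(self, small_counts):
        assert np.allclose(_tm(small_counts, "chi_square").data.to_numpy(),
                           oracle.chi_square_cells(small_counts.to_numpy()), atol=1e-8)

    def test_clr(self, small_counts):
        assert np.allclose(_tm(small_counts, "clr").data.to_numpy(),
                           oracle.clr_rows(small_counts.to_numpy(), 1.0), atol=1e-8)

    def test_rclr(self, small_counts):
        assert np.allclose(_tm(small_counts, "rclr").data.to_numpy(),
                           oracle.rclr_rows(small_counts.to_numpy()), atol=1e-8)

    def test_gmpr_factors(self, small_counts):
        assert np.allclose(gmpr_size_factors(small_counts.to_numpy(dtype=float)),
                           oracle.gmpr_factors(small_counts.to_numpy()), atol=1e-8)

    def test_kmer(self, small_counts, annotations_10):
        seqs = [annotations_10.sequences[t] for t in small_counts.columns]
        mine = _tm(small_counts, "kmer", sequences=annotations_10.sequences,
                   kmer_k=3).data.to_numpy()
        assert np.allclose(mine, oracle.kmer_rows(small_counts.to_numpy(), seqs, 3),
                           atol=1e-8)

    def test_rarefy_distribution(self, small_counts):
        """Rarefied rows are valid subsamples: exact depth, bounded by the
        original counts, and unbiased in expectation over repeats."""
        x = small_counts.to_numpy()
        depth = int(x.sum(axis=1).min())
        draws = np.array([
            _tm(small_counts, "rarefy", seed=s).data.to_numpy()
            for s in range(200)])
        assert (draws.sum(axis=2) == depth).all()
        assert (draws <= x[None, :, :]).all()
        expected = x / x.sum(axis=1, keepdims=True) * depth
        assert np.allclose(draws.mean(axis=0), expected,
                           atol=4 * np.sqrt(expected.max()) / np.sqrt(200) + 0.3)


class TestReferenceImplementations:
    """Model-based normalizations against their R reference packages,
    frozen from edgeR 4.0 runs on the same fixture matrix."""

    def test_tmm_matches_edger(self, small_counts):
        expected = [0.91042611, 0.85959644, 1.58171026, 0.94682232,
                    0.84740647, 1.00687021]
        factors = tmm_norm_factors(small_counts.to_numpy(dtype=float))
        assert np.allclose(factors, expected, atol=1e-7)

    def test_tmmwsp_matches_edger(self, small_counts):
        expected = [0.79165032, 0.89266918, 1.72125277, 0.95431970,
                    0.82388792, 1.04560918]
        factors = tmm_norm_factors(small_counts.to_numpy(dtype=float),
                                   singleton_pairing=True)
        assert np.allclose(factors, expected, atol=1e-7)

    def test_live_edger_crosscheck(self, small_counts, tmp_path):
        """Recompute the factors with edgeR at test time (R is part of the
        toolchain) and compare both TMM variants."""
        import subprocess

        mat = tmp_path / "m.tsv"
        np.savetxt(mat, small_counts.to_numpy(), fmt="%d", delimiter="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.table("{mat}"));'
            'cat(calcNormFactors(DGEList(counts=t(x)), method="TMM")$samples$norm.factors, "\\n");'
            'cat(calcNormFactors(DGEList(counts=t(x)), method="TMMwsp")$samples$norm.factors, "\\n")')
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, check=True)
        lines = proc.stdout.strip().splitlines()
        tmm_ref = np.array([float(v) for v in lines[0].split()])
        wsp_ref = np.array([float(v) for v in lines[1].split()])
        x = small_counts.to_numpy(dtype=float)
        assert np.allclose(tmm_norm_factors(x), tmm_ref, atol=1e-6)
        assert np.allclose(tmm_norm_factors(x, singleton_pairing=True),
                           wsp_ref, atol=1e-6)


class TestInvariants:
    @pytest.mark.parametrize("method", ["clr", "rclr"])
    def test_log_ratio_rows_sum_to_zero(self, small_counts, method):
        data = _tm(small_counts, method).data.to_numpy()
        if method == "rclr":
            sums = np.array([row[small_counts.to_numpy()[i] > 0].sum()
                             for i, row in enumerate(data)])
        else:
            sums = data.sum(axis=1)
        assert np.allclose(sums, 0.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["prop", "hellinger"])
    def test_scale_invariance_per_sample(self, small_counts, method):
        scaled = small_counts.copy()
        scaled.iloc[0] *= 7
        a = _tm(small_counts, method).data.to_numpy()[0]
        b = _tm(scaled, method).data.to_numpy()[0]
        assert np.allclose(a, b, atol=1e-10)

    def test_chi_square_global_scale_invariance(self, small_counts):
        a = _tm(small_counts, "chi_square").data.to_numpy()
        b = _tm(small_counts * 3, "chi_square").data.to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_rarefy_full_depth_is_identity(self):
        counts = pd.DataFrame([[4, 6, 10], [4, 6, 10]], index=["a", "b"],
                              columns=list("xyz"))
        out = _tm(counts, "rarefy", rarefy_depth=20).data
        assert np.array_equal(out.to_numpy(), counts.to_numpy())

    def test_rarefy_rows_sum_to_depth(self, small_counts):
        out = _tm(small_counts, "rarefy", rarefy_depth=50).data.to_numpy()
        assert (out.sum(axis=1) == 50).all()

    def test_gmpr_identical_samples_equal_factors(self):
        x = np.array([[3, 5, 7, 2], [3, 5, 7, 2], [6, 10, 14, 4]], dtype=float)
        s = gmpr_size_factors(x)
        assert np.isclose(s[0], s[1])

    def test_gmpr_factor_scales_with_sample(self, small_counts):
        x = small_counts.to_numpy(dtype=float)
        scaled = x.copy()
        scaled[3] *= 5
        assert np.isclose(gmpr_size_factors(scaled)[3],
                          5 * gmpr_size_factors(x)[3])

    def test_kmer_rows_sum_to_one(self, small_counts, annotations_10):
        out = _tm(small_counts, "kmer",
                  sequences=annotations_10.sequences).data.to_numpy()
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_vst_finite_and_monotone_in_counts(self, small_counts):
        out = _tm(small_counts, "vst").data.to_numpy()
        assert np.isfinite(out).all()
        # within one sample, a larger count never maps to a smaller value
        x = small_counts.to_numpy()
        for i in range(x.shape[0]):
            order = np.argsort(x[i])
            assert (np.diff(out[i, order]) >= -1e-9).all()

    def test_css_factors_positive(self, small_counts):
        assert (css_factors(small_counts.to_numpy(dtype=float)) > 0).all()

    def test_median_of_ratios_centred(self, small_counts):
        s = median_of_ratios_factors(small_counts.to_numpy(dtype=float))
        assert np.isclose(np.exp(np.mean(np.log(s))), 1.0)

    def test_wrench_groups_accepted(self, small_counts):
        groups = pd.Series(["a", "a", "a", "b", "b", "b"],
                           index=small_counts.index)
        out = _tm(small_counts, "wrench", wrench_groups=groups).data.to_numpy()
        assert np.isfinite(out).all() and (out >= 0).all()


class TestErrors:
    def test_rarefy_depth_too_large_names_sample(self, small_counts):
        with pytest.raises(ValueError, match="s"):
            _tm(small_counts, "rarefy", rarefy_depth=10**9)

    def test_clr_zero_pseudocount_with_zeros(self, small_counts):
        with pytest.raises(ValueError, match="pseudocount"):
            _tm(small_counts, "clr", clr_pseudocount=0)

    def test_kmer_without_sequences(self, small_counts):
        with pytest.raises(ValueError, match="sequences"):
            _tm(small_counts, "kmer")

    def test_unknown_method(self, small_counts):
        from sedabench.datatypes import ConfigurationError
        with pytest.raises(ConfigurationError):
            sb.TransformOptions(method="magic")
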