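"""Core signature model and the four connectivity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sigconn
from sigconn import (
    GeneListQuery,
    Signature,
    SignatureLibrary,
    UpDownQuery,
    connect_query,
    extreme_pearson,
    extreme_signature,
    random_set_score,
    signed_significance,
    updown_correlation,
    weighted_correlation,
)
from sigconn.exceptions import (
    InsufficientOverlapError,
    NoOverlapError,
    ParameterError,
    QueryTypeError,
    UndefinedCorrelationError,
    ValidationError,
)
from conftest import random_signature


# ---------------------------------------------------------------------------
# signature model


class TestSignatureValidation:
    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Signature(["A", "A"], [1.0, 2.0], [0.5, 0.5])

    @pytest.mark.parametrize("bad_p", [0.0, -0.1, 1.5, np.nan])
    def test_rejects_p_outside_unit_interval(self, bad_p):
        with pytest.raises(ValidationError, match="p-values"):
            Signature(["A", "B"], [1.0, 2.0], [0.5, bad_p])

    def test_rejects_nonfinite_d(self):
        with pytest.raises(ValidationError, match="non-finite"):
            Signature(["A", "B"], [1.0, np.inf], [0.5, 0.5])


# ---------------------------------------------------------------------------
# signed significance and extreme tails


class TestSignedSignificance:
    @pytest.mark.parametrize(
        "d,p,expected",
        [(2.0, 0.01, 2.0), (-1.5, 0.1, -1.0), (0.5, 1.0, 0.0)],
    )
    def test_exact_values(self, d, p, expected):
        sig = Signature(["A", "B"], [d, 1.0], [p, 0.5])
        assert signed_significance(sig).s[0] == pytest.approx(expected, abs=1e-15)

    def test_missing_p_routes_to_weighted_path(self):
        sig = Signature(["A", "B", "C"], [1.0, 2.0, 3.0], p=None)
        with pytest.raises(QueryTypeError, match="weighted"):
            signed_significance(sig)

    def test_sign_follows_d(self, rng):
        sig = random_signature(rng, 50)
        s = signed_significance(sig).s
        nz = sig.p < 1
        assert np.all(np.sign(s[nz]) == np.sign(sig.d[nz]))


class TestExtremeSignature:
    def test_single_most_extreme_each_side(self):
        e = extreme_signature(np.array([3.0, -2.0, 1.0, -1.0]), k=1).e
        assert e.tolist() == [3.0, -2.0, 0.0, 0.0]

    def test_boundary_ties_retained(self):
        e = extreme_signature(np.array([2.0, 2.0, 1.0, -3.0]), k=1).e
        assert e.tolist() == [2.0, 2.0, 0.0, -3.0]

    def test_default_tail_keeps_200_of_978_distinct(self, rng):
        s = rng.permutation(np.linspace(-5, 5, 978))
        e = extreme_signature(s)  # default k=100
        assert np.count_nonzero(e.e) == 200

    def test_small_vector_returned_unchanged_with_warning(self):
        s = np.array([1.0, -1.0, 2.0])
        with pytest.warns(UserWarning, match="extreme"):
            e = extreme_signature(s, k=2)
        assert e.e.tolist() == s.tolist()

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            extreme_signature(np.array([1.0, 2.0]), k=0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 8))
    def test_nonzeros_equal_original_entries(self, seed, k):
        s = np.random.default_rng(seed).normal(size=40)
        e = extreme_signature(s, k=k).e
        nz = e != 0
        assert np.array_equal(e[nz], s[nz])
        assert np.count_nonzero(nz) >= min(2 * k, 40)


# ---------------------------------------------------------------------------
# extreme Pearson


def brute_force_extreme_pearson(a, b, k):
    """Independent oracle: explicit tail selection then textbook Pearson."""
    sa = np.sign(a.d) * -np.log10(a.p)
    sb = np.sign(b.d) * -np.log10(b.p)
    out = []
    for s in (sa, sb):
        srt = sorted(s)
        top, bot = srt[len(s) - k], srt[k - 1]
        out.append(np.array([v if (v >= top or v <= bot) else 0.0 for v in s]))
    return stats.pearsonr(out[0], out[1]).statistic


class TestExtremePearson:
    def test_self_correlation_is_one(self, rng):
        a = random_signature(rng, 30)
        assert extreme_pearson(a, a, k=5).score == pytest.approx(1.0)

    def test_negated_d_gives_minus_one(self, rng):
        a = random_signature(rng, 30, sig_id="a")
        b = Signature(a.gene_ids, -a.d, a.p, {"signature_id": "b"})
        assert extreme_pearson(a, b, k=5).score == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            a = random_signature(rng, 20, sig_id="a")
            b = random_signature(rng, 20, sig_id="b")
            got = extreme_pearson(a, b, k=5).score
            assert got == pytest.approx(brute_force_extreme_pearson(a, b, 5), abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = random_signature(rng, 40, sig_id="a")
        b = random_signature(rng, 40, sig_id="b")
        ra = extreme_pearson(a, b, k=7)
        rb = extreme_pearson(b, a, k=7)
        assert ra.score == pytest.approx(rb.score, abs=1e-14)
        assert ra.p_value == pytest.approx(rb.p_value, abs=1e-14)

    def test_insufficient_overlap(self, rng):
        a = random_signature(rng, 10, prefix="X")
        b = random_signature(rng, 10, prefix="Y")
        with pytest.raises(InsufficientOverlapError):
            extreme_pearson(a, b)

    def test_zero_variance_raises(self):
        a = Signature(["A", "B", "C"], [1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        with pytest.raises(UndefinedCorrelationError):
            extreme_pearson(a, a, k=1)

    def test_union_nonzero_support(self, rng):
        a = random_signature(rng, 50, sig_id="a")
        b = random_signature(rng, 50, sig_id="b")
        res = extreme_pearson(a, b, k=3, extreme_support="union_nonzero")
        assert 6 <= res.n_genes_used <= 12
        assert -1 <= res.score <= 1


# ---------------------------------------------------------------------------
# weighted correlation


def weighted_corr_oracle(x, y, w):
    """Direct weighted-covariance formula."""
    xm = np.sum(w * x) / np.sum(w)
    ym = np.sum(w * y) / np.sum(w)
    cov = np.sum(w * (x - xm) * (y - ym))
    return cov / np.sqrt(np.sum(w * (x - xm) ** 2) * np.sum(w * (y - ym) ** 2))


class TestWeightedCorrelation:
    def test_uniform_weights_equal_plain_pearson(self, rng):
        n = 40
        ids = [f"G{i}" for i in range(n)]
        p = np.full(n, 0.05)
        a = Signature(ids, rng.normal(size=n), p)
        b = Signature(ids, rng.normal(size=n), p)
        res = weighted_correlation(a, b)
        assert res.score == pytest.approx(stats.pearsonr(a.d, b.d).statistic, abs=1e-14)

    def test_query_without_p_uses_library_weights(self, rng):
        lib = random_signature(rng, 30, sig_id="lib")
        q = Signature(lib.gene_ids, rng.normal(size=30), p=None)
        res = weighted_correlation(q, lib)
        w = -np.log10(lib.p)
        assert res.score == pytest.approx(weighted_corr_oracle(q.d, lib.d, w), abs=1e-13)

    def test_product_weights_match_oracle(self, rng):
        a = random_signature(rng, 30, sig_id="a")
        b = random_signature(rng, 30, sig_id="b")
        w = (-np.log10(a.p)) * (-np.log10(b.p))
        res = weighted_correlation(a, b)
        assert res.score == pytest.approx(weighted_corr_oracle(a.d, b.d, w), abs=1e-13)

    def test_scaled_d_gives_one(self, rng):
        lib = random_signature(rng, 25, sig_id="lib")
        q = Signature(lib.gene_ids, 2.0 * lib.d, lib.p)
        assert weighted_correlation(q, lib).score == pytest.approx(1.0)

    def test_all_zero_weights_error(self):
        ids = ["A", "B", "C"]
        lib = Signature(ids, [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        q = Signature(ids, [1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        with pytest.raises(sigconn.exceptions.InsufficientInformationError):
            weighted_correlation(q, lib)

    def test_zero_weight_genes_drop_out(self, rng):
        ids = [f"G{i}" for i in range(10)]
        d_lib = rng.normal(size=10)
        p_lib = np.r_[np.full(5, 0.01), np.full(5, 1.0)]  # half carry no weight
        lib = Signature(ids, d_lib, p_lib)
        q = Signature(ids, rng.normal(size=10), p=None)
        assert weighted_correlation(q, lib).n_genes_used == 5


# ---------------------------------------------------------------------------
# up/down correlation


class TestUpDownCorrelation:
    def test_perfect_concordance(self):
        lib = Signature(["A", "B", "C", "D"], [1.0, 1.0, -1.0, -1.0],
                        [0.01, 0.01, 0.01, 0.01])
        q = UpDownQuery(up={"A", "B"}, down={"C", "D"})
        assert updown_correlation(q, lib).score == pytest.approx(1.0)

    def test_swapped_labels_negate_score_keep_p(self, rng):
        lib = random_signature(rng, 30)
        genes = lib.gene_ids.tolist()
        q = UpDownQuery(up=set(genes[:8]), down=set(genes[8:15]))
        qswap = UpDownQuery(up=q.down, down=q.up)
        r1, r2 = updown_correlation(q, lib), updown_correlation(qswap, lib)
        assert r1.score == pytest.approx(-r2.score, abs=1e-14)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-14)

    def test_p_equals_two_sample_ttest(self, rng):
        for _ in range(50):
            lib = random_signature(rng, 30)
            genes = lib.gene_ids.tolist()
            n_up = rng.integers(2, 15)
            n_dn = rng.integers(2, 15)
            picks = rng.choice(30, size=n_up + n_dn, replace=False)
            q = UpDownQuery(up={genes[i] for i in picks[:n_up]},
                            down={genes[i] for i in picks[n_up:]})
            res = updown_correlation(q, lib)
            d_up = lib.d[picks[:n_up]]
            d_dn = lib.d[picks[n_up:]]
            expect = stats.ttest_ind(d_up, d_dn, equal_var=True).pvalue
            assert res.p_value == pytest.approx(expect, rel=1e-10)

    def test_one_sided_query_falls_back_to_random_set(self, rng):
        lib = random_signature(rng, 30)
        genes = lib.gene_ids.tolist()
        q = UpDownQuery(up=set(genes[:5]), down={"NOT_IN_LIB"})
        with pytest.warns(UserWarning, match="Random Set"):
            res = updown_correlation(q, lib)
        assert res.metric == "random_set"

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            UpDownQuery(up={"A"}, down={"A"})


# ---------------------------------------------------------------------------
# Random Set gene-list metric


class TestRandomSetScore:
    def test_single_gene_variance(self, rng):
        lib = random_signature(rng, 50)
        res = random_set_score(GeneListQuery({lib.gene_ids[0]}), lib)
        # m=1: sigma_m^2 = sigma^2, so z = (g_i - mu)/sigma exactly
        g = -np.log10(lib.p)
        expect = (g[0] - g.mean()) / g.std()
        assert res.score == pytest.approx(expect, abs=1e-12)

    def test_constant_scores_give_null_result(self):
        lib = Signature(["A", "B", "C", "D"], [1.0, -1.0, 2.0, 0.5],
                        [0.1, 0.1, 0.1, 0.1])
        res = random_set_score(GeneListQuery({"A", "B"}), lib)
        assert res.score == 0.0 and res.p_value == 1.0

    def test_monte_carlo_moments(self, rng):
        lib = random_signature(rng, 50)
        g = -np.log10(lib.p)
        n, m = 50, 8
        draws = np.array([
            g[rng.choice(n, size=m, replace=False)].mean() for _ in range(100_000)
        ])
        mu, var = g.mean(), g.var() * (n - m) / ((n - 1) * m)
        assert draws.mean() == pytest.approx(mu, rel=0.01)
        assert draws.var() == pytest.approx(var, rel=0.01)

    def test_permuting_nonmember_scores_leaves_z(self, rng):
        lib = random_signature(rng, 40)
        members = set(lib.gene_ids[:6].tolist())
        res1 = random_set_score(GeneListQuery(members), lib)
        # permute d/p among non-member genes: statistic must not move
        idx = np.arange(40)
        out = idx[6:]
        perm = rng.permutation(out)
        d2, p2 = lib.d.copy(), lib.p.copy()
        d2[out], p2[out] = lib.d[perm], lib.p[perm]
        res2 = random_set_score(GeneListQuery(members), Signature(lib.gene_ids, d2, p2))
        assert res1.score == pytest.approx(res2.score, abs=1e-12)

    def test_no_overlap_error(self, rng):
        lib = random_signature(rng, 10)
        with pytest.raises(NoOverlapError):
            random_set_score(GeneListQuery({"ABSENT"}), lib)

    def test_full_universe_error(self, rng):
        lib = random_signature(rng, 10)
        with pytest.raises(sigconn.exceptions.DegenerateSetError):
            random_set_score(GeneListQuery(set(lib.gene_ids.tolist())), lib)


# ---------------------------------------------------------------------------
# query dispatch, ranking, FDR


class TestConnectQuery:
    def _library(self, rng, n_sigs=20, n_genes=60):
        sigs = [random_signature(rng, n_genes, sig_id=f"s{i:03d}") for i in range(n_sigs)]
        return SignatureLibrary(sigs)

    def test_self_query_ranks_first_with_score_one(self, rng):
        lib = self._library(rng)
        query = lib.signatures[7]
        res = connect_query(query, lib, k=10)
        assert res[0].library_signature_id == "s007"
        assert res[0].score == pytest.approx(1.0)
        assert res[0].metric == "extreme_pearson"

    def test_metric_dispatch_by_query_type(self, rng):
        lib = self._library(rng)
        genes = lib.gene_ids.tolist()
        full = Signature(lib.gene_ids, rng.normal(size=60),
                         np.full(60, 0.1), {"signature_id": "user"})
        cases = [
            (full, None, "weighted_correlation"),
            (Signature(lib.gene_ids, rng.normal(size=60)), None, "weighted_correlation"),
            (UpDownQuery(set(genes[:5]), set(genes[5:10])), None, "updown_correlation"),
            (GeneListQuery(set(genes[:8])), None, "random_set"),
        ]
        for query, qtype, metric in cases:
            res = connect_query(query, lib, k=10, query_type=qtype)
            assert {r.metric for r in res} == {metric}

    def test_bh_fdr_monotone_and_above_p(self, rng):
        lib = self._library(rng, n_sigs=30)
        q = Signature(lib.gene_ids, rng.normal(size=60), np.full(60, 0.05))
        res = connect_query(q, lib)
        fdrs = [r.fdr for r in res]
        ps = [r.p_value for r in res]
        assert fdrs == sorted(fdrs) or all(
            f2 >= f1 - 1e-15 for f1, f2 in zip(fdrs, fdrs[1:])
        )
        assert fdrs[0] >= ps[0]
        assert ps == sorted(ps)

    def test_planted_partner_ranks_first(self):
        query, lib, plant = sigconn.synth.simulate_library(
            n_genes=400, n_null=99, planted_rhos=(0.9,), seed=11
        )
        res = connect_query(query, lib)
        assert res[0].library_signature_id == plant["signature_id"].iloc[0]

    def test_unknown_query_type(self, rng):
        lib = self._library(rng)
        with pytest.raises(QueryTypeError):
            connect_query(object(), lib)
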