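import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pmpscan import runs as R


def _sim_table(sims):
    return pd.DataFrame({"sim": np.asarray(sims, dtype=float),
                         "n_used": 60},
                        index=pd.Index([f"cg{i}" for i in range(len(sims))],
                                       name="locus_id"))


def _annotation(n, chrom="chr1", cgi=None):
    return pd.DataFrame({
        "locus_id": [f"cg{i}" for i in range(n)],
        "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
        "pos": np.arange(n) * 1000,
        "gene": [f"G{i}" for i in range(n)],
        "tss": np.arange(n) * 1000 - 100,
        "strand": ["+"] * n,
        "cgi": cgi if cgi is not None else ["CGI"] * n,
        "gene_class": ["OTHER"] * n,
    })


def _vector(bits, chroms=None):
    bits = np.asarray(bits, dtype=np.uint8)
    n = len(bits)
    if chroms is None:
        chroms = np.array(["chr1"] * n, dtype=object)
    return R.BinaryGenomeVector(
        subset="ALL", locus_ids=np.array([f"cg{i}" for i in range(n)]),
        chroms=np.asarray(chroms, dtype=object), bits=bits, threshold=0.0)


class TestBinarize:
    def test_top_20_percent_of_ten(self):
        sims = [0.9, 0.7, 0.5, 0.3, 0.1, 0.0, -0.1, -0.2, -0.3, -0.4]
        v = R.binarize_top_percentile(_sim_table(sims), _annotation(10),
                                      subset="ALL", pct=20, scope="GLOBAL")
        assert v.n_ones == 2
        marked = set(v.locus_ids[v.bits == 1])
        assert marked == {"cg0", "cg1"}

    def test_threshold_ties_all_included(self):
        sims = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        v = R.binarize_top_percentile(_sim_table(sims), _annotation(10),
                                      subset="ALL", pct=20, scope="GLOBAL")
        assert v.n_ones == 3  # ones may exceed pct% under ties

    def test_per_subset_scope_gives_each_subset_its_share(self):
        # CGI sims uniformly higher: global scope starves NON_CGI of ones
        cgi = ["CGI"] * 10 + ["NON_CGI"] * 10
        sims = list(np.linspace(0.5, 0.9, 10)) + list(np.linspace(-0.5, 0.1, 10))
        ann = _annotation(20, cgi=cgi)
        for subset in ("CGI", "NON_CGI"):
            v = R.binarize_top_percentile(_sim_table(sims), ann,
                                          subset=subset, pct=20,
                                          scope="PER_SUBSET")
            assert v.n_ones == 2
        v_glob = R.binarize_top_percentile(_sim_table(sims), ann,
                                           subset="NON_CGI", pct=20,
                                           scope="GLOBAL")
        assert v_glob.n_ones == 0

    def test_missing_sims_dropped_before_ordering(self):
        sims = [0.9, np.nan, 0.5, 0.3]
        v = R.binarize_top_percentile(_sim_table(sims), _annotation(4),
                                      subset="ALL", pct=50, scope="GLOBAL")
        assert len(v) == 3

    def test_genome_order_within_subset(self):
        ann = _annotation(6, chrom=["chr2", "chr2", "chr1", "chr1",
                                    "chrX", "chr10"])
        v = R.binarize_top_percentile(_sim_table([0.1] * 6), ann,
                                      subset="ALL", pct=50, scope="GLOBAL")
        assert list(v.chroms) == ["chr1", "chr1", "chr2", "chr2", "chr10",
                                  "chrX"]


class TestFindRuns:
    def test_maximal_runs_and_mean(self):
        runs = R.find_runs(_vector([0, 1, 1, 0, 1, 1, 1]))
        assert list(runs["length"]) == [2, 3]
        assert R.run_length_stats(runs)["mean"] == pytest.approx(2.5)

    def test_runs_break_at_chromosome_boundary(self):
        v = _vector([1, 1], chroms=["chr1", "chr2"])
        runs = R.find_runs(v)
        assert list(runs["length"]) == [1, 1]

    def test_all_zero_vector(self):
        runs = R.find_runs(_vector([0, 0, 0]))
        assert len(runs) == 0
        stats = R.run_length_stats(runs)
        assert stats["n_runs"] == 0 and np.isnan(stats["mean"])

    def test_min_len_filter(self):
        runs = pd.DataFrame({"chrom": "chr1", "start_index": [0, 2, 4, 8],
                             "start_locus": "x",
                             "length": [1, 1, 2, 3]})
        assert R.run_length_stats(runs, min_len=1)["mean"] == pytest.approx(1.75)
        assert R.run_length_stats(runs, min_len=2)["mean"] == pytest.approx(2.5)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200),
           st.integers(1, 3))
    def test_run_lengths_sum_to_popcount(self, bits, n_chrom):
        chroms = [f"chr{1 + (i * n_chrom) // len(bits)}"
                  for i in range(len(bits))]
        v = _vector(bits, chroms=chroms)
        runs = R.find_runs(v)
        assert runs["length"].sum() == sum(bits)


class TestPermutationNull:
    def test_ones_count_preserved_and_closed_form(self):
        rng = np.random.default_rng(5)
        bits = np.zeros(2000, dtype=np.uint8)
        bits[rng.choice(2000, 400, replace=False)] = 1
        v = _vector(bits)
        null = R.permutation_null_runs(v, n_perm=100, seed=9)
        expected = R.expected_null_mean_run_length(2000, 400)
        se = null.null_sd_run_length / np.sqrt(null.n_perm)
        assert abs(null.null_mean_run_length - expected) < 3 * se + 1e-3

    def test_clustered_vector_beats_null(self):
        bits = np.zeros(1000, dtype=np.uint8)
        for start in range(0, 1000, 100):
            bits[start:start + 20] = 1  # 20-long planted blocks
        v = _vector(bits)
        null = R.permutation_null_runs(v, n_perm=50, seed=2)
        assert null.comparison is not None
        assert null.comparison.p < 1e-6
        obs_mean = R.run_length_stats(R.find_runs(v))["mean"]
        assert obs_mean > null.null_mean_run_length


class TestClassMembership:
    def test_class_inside_long_run_scores_one(self):
        ann = _annotation(10)
        ann.loc[2:4, "gene_class"] = "CTA"
        v = _vector([0, 0, 1, 1, 1, 0, 0, 0, 0, 0])
        res = R.class_run_membership(v, ann, "CTA", min_len=2, n_perm=50,
                                     seed=0)
        assert res.fraction_in_runs == 1.0
        assert res.n_class_loci == 3

    def test_class_all_zero_scores_zero(self):
        ann = _annotation(10)
        ann.loc[7:9, "gene_class"] = "CTX"
        v = _vector([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        res = R.class_run_membership(v, ann, "CTX", min_len=2, n_perm=50,
                                     seed=0)
        assert res.fraction_in_runs == 0.0

    def test_degenerate_null_flagged(self):
        # every bit is one: every permutation gives fraction 1 -> sd 0
        ann = _annotation(4)
        ann.loc[0:1, "gene_class"] = "CTA"
        v = _vector([1, 1, 1, 1])
        res = R.class_run_membership(v, ann, "CTA", min_len=2, n_perm=20,
                                     seed=0)
        assert np.isnan(res.z) and np.isnan(res.p)
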