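import numpy as np
import pytest

from reefmito.distances import DistanceMatrix, pairwise_difference_matrix
from reefmito.errors import StratumError
from reefmito.popstruct import amova, amova_permutation_p, chisq_regional_homogeneity
from reefmito.haplogroups import assign_haplogroups
from reefmito.seqio import Alignment

from conftest import make_meta, random_alignment
from oracles import amova_ems_oracle


def two_reef_toy():
    """Two monomorphic, mutually distinct reefs (one region each)."""
    ids, seqs, reefs, regions = [], [], [], []
    for i in range(8):
        ids.append(f"a{i}")
        seqs.append("AAAATTTT")
        reefs.append("R1")
        regions.append("N")
    for i in range(8):
        ids.append(f"b{i}")
        seqs.append("GGGGTTTT")
        reefs.append("R2")
        regions.append("S")
    aln = Alignment(ids, seqs)
    meta = make_meta(ids, reefs, regions)
    return pairwise_difference_matrix(aln), meta


def random_design(rng, n, n_regions, n_reefs):
    """Random toy dataset with every reef and region non-empty."""
    aln = random_alignment(rng, n=n, L=20, missing_rate=0.1)
    region_of_reef = np.concatenate(
        [np.arange(n_regions), rng.integers(0, n_regions, n_reefs - n_regions)]
    )
    reef = np.concatenate(
        [np.arange(n_reefs), rng.integers(0, n_reefs, n - n_reefs)]
    )
    rng.shuffle(reef)
    meta = make_meta(
        aln.ids,
        [f"R{r}" for r in reef],
        [f"G{region_of_reef[r]}" for r in reef],
    )
    return aln, meta, reef, region_of_reef


class TestAmova:
    def test_perfectly_separated_reefs(self):
        dm, meta = two_reef_toy()
        res = amova(dm, meta)
        assert res.sigma["c"] == pytest.approx(0.0)
        assert res.phi["PhiST"] == pytest.approx(1.0)
        # one reef per region: among-reefs df is 0, PhiPR undefined, PhiST == PhiRT
        assert res.phi["PhiPR"] is None
        assert res.phi["PhiRT"] == pytest.approx(res.phi["PhiST"])

    def test_all_identical_undefined(self):
        ids = [f"c{i}" for i in range(6)]
        aln = Alignment(ids, ["ACGT"] * 6)
        meta = make_meta(ids, ["R1", "R1", "R1", "R2", "R2", "R2"],
                         ["N", "N", "N", "S", "S", "S"])
        res = amova(pairwise_difference_matrix(aln), meta)
        assert res.undefined
        assert all(v == 0 for v in res.sigma.values())
        assert all(v is None for v in res.phi.values())

    def test_additivity_and_df(self, palau_like):
        aln, meta, _ = palau_like
        res = amova(pairwise_difference_matrix(aln), meta)
        t = res.table.set_index("Source")
        assert t.loc["Total", "df"] == aln.n - 1
        assert (
            t.loc[["Among Regions", "Among Reefs", "Within Reefs"], "df"].sum()
            == t.loc["Total", "df"]
        )
        assert (
            t.loc[["Among Regions", "Among Reefs", "Within Reefs"], "SS"].sum()
            == pytest.approx(t.loc["Total", "SS"])
        )
        assert t["pct"].iloc[:3].sum() == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_components_match_ems_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(9, 13))
        aln, meta, reef, region_of_reef = random_design(
            rng, n=n, n_regions=2, n_reefs=4
        )
        res = amova(pairwise_difference_matrix(aln), meta)
        # oracle works on the same colony order with plain-Python loops
        rows = meta.aligned_to(aln.ids)
        reefs = sorted(rows["reef"].unique())
        reef_idx = [reefs.index(r) for r in rows["reef"]]
        region_of = [
            sorted(rows["region"].unique()).index(
                rows.loc[rows["reef"] == r, "region"].iloc[0]
            )
            for r in reefs
        ]
        D = pairwise_difference_matrix(aln).D
        a, b, c = amova_ems_oracle(D.tolist(), reef_idx, region_of)
        assert res.sigma["a"] == pytest.approx(a, abs=1e-10)
        assert res.sigma["b"] == pytest.approx(b, abs=1e-10)
        assert res.sigma["c"] == pytest.approx(c, abs=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        aln, meta, _, _ = random_design(rng, n=12, n_regions=2, n_reefs=4)
        res1 = amova(pairwise_difference_matrix(aln), meta)
        renamed = make_meta(
            aln.ids,
            ["X" + r for r in meta.df["reef"]],
            ["Y" + g for g in meta.df["region"]],
        )
        res2 = amova(pairwise_difference_matrix(aln), renamed)
        assert res1.phi == pytest.approx(res2.phi)

    def test_single_reef_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        meta = make_meta(["a", "b"], ["R1", "R1"], ["N", "N"])
        with pytest.raises(StratumError):
            amova(pairwise_difference_matrix(aln), meta)


class TestPermutationP:
    def test_perfect_separation_min_p(self):
        dm, meta = two_reef_toy()
        B = 199
        res = amova_permutation_p(dm, meta, B=B, seed=0)
        assert res.p_values["PhiST"] == pytest.approx(1 / (B + 1))

    def test_single_region_phirt_not_applicable(self):
        ids = [f"c{i}" for i in range(8)]
        aln = Alignment(ids, ["AAAA"] * 4 + ["TTTT"] * 4)
        meta = make_meta(ids, ["R1"] * 4 + ["R2"] * 4, ["N"] * 8)
        res = amova_permutation_p(pairwise_difference_matrix(aln), meta, B=99, seed=0)
        assert res.p_values["PhiRT"] is None
        assert res.p_values["PhiPR"] is not None

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        aln, meta, _, _ = random_design(rng, n=12, n_regions=2, n_reefs=4)
        dm = pairwise_difference_matrix(aln)
        r1 = amova_permutation_p(dm, meta, B=99, seed=123)
        r2 = amova_permutation_p(dm, meta, B=99, seed=123)
        assert r1.p_values == r2.p_values

    def test_exchangeable_p_not_extreme(self):
        # With colonies assigned to reefs at random, p should not concentrate
        # near 0: check it exceeds 0.05 for a clearly unstructured toy.
        rng = np.random.default_rng(12)
        aln, meta, _, _ = random_design(rng, n=12, n_regions=2, n_reefs=4)
        res = amova_permutation_p(pairwise_difference_matrix(aln), meta, B=199, seed=5)
        assert res.p_values["PhiST"] > 0.01


class TestChisqHomogeneity:
    def test_proportional_distribution_is_null(self):
        # group spread exactly proportionally to regional totals
        ids = [f"c{i}" for i in range(8)]
        aln = Alignment(ids, ["AAAA"] * 4 + ["TTTT"] * 4)
        # regions sized 4 and 4; the group of 4 puts 2 in each
        meta = make_meta(
            ids,
            ["R1", "R1", "R2", "R2"] * 2,
            ["N", "N", "S", "S"] * 2,
        )
        h, _ = assign_haplogroups(aln)
        out = chisq_regional_homogeneity(h, meta)
        assert np.allclose(out["chi2"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_concentrated_group_small_p(self):
        # 3-colony group all in one region of 7 equal regions: closed form
        # chi2 = sum (O-E)^2/E with E_j = 3/7 per region.
        ids = [f"c{i}" for i in range(21)]
        aln = Alignment(ids, ["AAAA"] * 3 + ["TTTT"] * 18)
        regions = [f"G{i}" for i in range(7) for _ in range(3)]
        reefs = [f"R{i}" for i in range(7) for _ in range(3)]
        meta = make_meta(ids, reefs, regions)
        h, _ = assign_haplogroups(aln)
        out = chisq_regional_homogeneity(h, meta).set_index("size")
        row = out.loc[3]
        expected_chi2 = (3 - 3 / 7) ** 2 / (3 / 7) + 6 * (3 / 7)
        assert row["chi2"] == pytest.approx(expected_chi2)
        assert row["p"] < 0.01
        assert row["low_expected"]

    def test_bh_correction_monotone(self, palau_like):
        aln, meta, _ = palau_like
        h, _ = assign_haplogroups(aln)
        out = chisq_regional_homogeneity(h, meta)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
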