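import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interactome_kit.motifs import (
    average_copy_trajectory,
    build_count_array,
    count_kmer_repeats,
    fisher_exact_one_sided,
    test_motif_expansion,
)
from interactome_kit.orthology import select_representative
from interactome_kit.synthetic_data import (
    AMINO_ACIDS,
    PlantedMotifSpec,
    simulate_proteomes,
)

from oracles import fisher_upper_tail_oracle, kmer_count_oracle


class TestCountKmers:
    def test_overlapping_homopolymer(self):
        assert count_kmer_repeats("KKKKK", k=3) == {"KKK": 3}

    def test_windows_with_x_excluded(self):
        assert count_kmer_repeats("AKXKA", k=3) == {}

    def test_terminal_stop_stripped(self):
        assert count_kmer_repeats("KKKK*", k=3) == {"KKK": 2}

    def test_bad_k_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert count_kmer_repeats("AK", k=3) == {}
        with pytest.warns(UserWarning):
            assert count_kmer_repeats("AK", k=0) == {}

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        letters = AMINO_ACIDS + "XU"
        seq = "".join(letters[i] for i in rng.integers(0, len(letters), size=200))
        assert count_kmer_repeats(seq, k=3) == kmer_count_oracle(seq, 3)

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet=AMINO_ACIDS + "XU", min_size=3, max_size=60))
    def test_count_conservation(self, seq):
        """Total counts equal window positions minus X/U-containing windows."""
        counts = count_kmer_repeats(seq, k=3)
        n_windows = len(seq) - 2
        n_excluded = sum(
            1 for i in range(n_windows) if set(seq[i : i + 3].upper()) & set("XU")
        )
        assert sum(counts.values()) == n_windows - n_excluded


class TestFisherOneSided:
    def test_degenerate_margin(self):
        assert fisher_exact_one_sided(0, 5, 0, 5) == 1.0

    def test_closed_form_perfect_split(self):
        assert fisher_exact_one_sided(5, 0, 0, 5) == pytest.approx(1 / 252)

    def test_matches_enumeration_oracle(self):
        assert fisher_exact_one_sided(3, 1, 1, 3) == pytest.approx(
            float(fisher_upper_tail_oracle(3, 1, 1, 3)), rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(-1, 2, 3, 4)


def build_test_array(n_groups=30, planted_extra=(0, 0, 1, 2, 3), seed=0, **kw):
    spec = PlantedMotifSpec("KKR", extra_copies_in_rbps=planted_extra)
    seqs, groups, rbps = simulate_proteomes(n_groups, [spec], seed=seed, **kw)
    reps = {
        org: {gid: select_representative(m, org) for gid, m in groups.groups.items()}
        for org in seqs
    }
    return build_count_array(reps, seqs, rbps), rbps


class TestBuildCountArray:
    def test_planted_counts_recovered_by_oracle(self):
        array, rbps = build_test_array(n_groups=10, seed=1)
        spec = PlantedMotifSpec("KKR", extra_copies_in_rbps=(0, 0, 1, 2, 3))
        seqs, groups, rbps2 = simulate_proteomes(10, [spec], seed=1)
        for gid in list(groups.groups)[:5]:
            pid = select_representative(groups.groups[gid], "human")
            expected = kmer_count_oracle(seqs["human"][pid], 3)
            got = array.counts.sel(group=gid, organism="human")
            for motif in expected:
                assert float(got.sel(motif=motif)) == expected[motif]

    def test_motif_axis_union(self):
        reps = {"yeast": {"OG1": "y1"}, "human": {"OG1": "h1"}}
        seqs = {"yeast": {"y1": "AAAA"}, "human": {"h1": "CCCC"}}
        array = build_count_array(reps, seqs, set(), organisms=("yeast", "human"))
        assert sorted(array.counts.coords["motif"].values) == ["AAA", "CCC"]

    def test_missing_representative_is_nan_slice(self):
        reps = {
            "yeast": {"OG1": "y1"},
            "human": {"OG1": "h1"},
            "fly": {"OG1": None},
        }
        seqs = {"yeast": {"y1": "AAAA"}, "human": {"h1": "AAAC"}, "fly": {}}
        array = build_count_array(
            reps, seqs, set(), organisms=("yeast", "human", "fly")
        )
        assert np.isnan(array.counts.sel(organism="fly").values).all()

    def test_missing_sequence_errors(self):
        reps = {"yeast": {"OG1": "y1"}, "human": {"OG1": "h1"}}
        seqs = {"yeast": {"y1": "AAAA"}, "human": {}}
        with pytest.raises(KeyError, match="h1"):
            build_count_array(reps, seqs, set(), organisms=("yeast", "human"))


class TestExpansionTest:
    def test_no_expansion_no_selection(self):
        array, _ = build_test_array(planted_extra=(0, 0, 0, 0, 0), seed=2)
        res = test_motif_expansion(array)
        assert int(res["selected"].sum()) <= 1  # null data: at most a stray hit

    def test_planted_motif_detected(self):
        array, _ = build_test_array(n_groups=100, seed=3)
        res = test_motif_expansion(array)
        assert "KKR" in set(res.loc[res["selected"], "motif"])

    def test_contingency_sums_to_universe(self):
        array, _ = build_test_array(n_groups=40, seed=4)
        res = test_motif_expansion(array)
        assert ((res["a"] + res["b"] + res["c"] + res["d"]) == 40).all()

    def test_all_rbp_universe_rejected(self):
        array, _ = build_test_array(n_groups=10, seed=5, rbp_fraction=1.0)
        with pytest.raises(ValueError):
            test_motif_expansion(array)

    def test_group_order_invariance(self):
        array, _ = build_test_array(n_groups=20, seed=6)
        res1 = test_motif_expansion(array)
        flipped = array.counts.isel(group=slice(None, None, -1))
        from interactome_kit.motifs import KmerCountArray

        array2 = KmerCountArray(counts=flipped, rbp_flag=array.rbp_flag.iloc[::-1])
        res2 = test_motif_expansion(array2)
        assert res1.set_index("motif")["p_raw"].equals(res2.set_index("motif")["p_raw"])


class TestTrajectory:
    def test_single_group_trajectory_is_its_counts(self):
        import pandas as pd
        import xarray as xr
        from interactome_kit.motifs import KmerCountArray

        counts = xr.DataArray(
            np.array([[[1.0, 1.0, 2.0, 3.0, 5.0]], [[0.0, 0.0, 0.0, 0.0, 0.0]]]),
            dims=("group", "motif", "organism"),
            coords={
                "group": ["OG1", "OG2"],
                "motif": ["KKR"],
                "organism": ["yeast", "worm", "fly", "fish", "human"],
            },
        )
        array = KmerCountArray(
            counts=counts, rbp_flag=pd.Series([True, False], index=["OG1", "OG2"])
        )
        traj = average_copy_trajectory(array, {"KKR"})
        assert list(traj["rbp"]) == [1, 1, 2, 3, 5]
        assert list(traj["non_rbp"]) == [0, 0, 0, 0, 0]

    def test_planted_rbp_trajectory_nondecreasing(self):
        array, _ = build_test_array(n_groups=60, seed=7)
        traj = average_copy_trajectory(array, {"KKR"})
        diffs = np.diff(traj["rbp"].to_numpy())
        assert (diffs >= -0.35).all()  # monotone planting up to background noise
        assert traj["rbp"].iloc[-1] > traj["rbp"].iloc[0] + 2

    def test_empty_motif_set_rejected(self):
        array, _ = build_test_array(n_groups=10, seed=8)
        with pytest.raises(ValueError):
            average_copy_trajectory(array, set())
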