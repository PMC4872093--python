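"""Conservation scoring, MI-APC couplings, selection and enrichment."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ispkit import msa as M
from ispkit import synthetic as syn
from ispkit.msa import Msa
from ispkit.synthetic import MsaSpec


def planted_msa(seed, n=200, length=100, n_pairs=10):
    half = length // 2
    pairs = [(i, i + half, {("K", "E"): 0.5, ("E", "K"): 0.5})
             for i in range(n_pairs)]
    spec = MsaSpec(n_seqs=n, length=length, conserved={half - 5: "W"},
                   coupled=pairs, seed=seed)
    ids, rows, truth = syn.simulate_msa(spec)
    return Msa(ids=ids, rows=rows), truth


class TestMsaContainer:
    def test_ragged_rows_rejected(self):
        with pytest.raises(M.MsaError):
            Msa(ids=["a", "b"], rows=["ACDE", "ACD"])

    def test_reference_map_numbers_nongap_columns(self):
        msa = Msa(ids=["ref", "x"], rows=["AC-DE", "AAAAA"])
        msa.build_ref_map("ref", ref_start=868)
        assert msa.ref_map == {0: 868, 1: 869, 3: 870, 4: 871}
        assert msa.columns_for_ref_range(869, 870) == [1, 3]
        with pytest.raises(M.MsaError):
            msa.columns_for_ref_range(100, 200)

    @pytest.mark.parametrize("fmt,text", [
        ("fasta", ">a\nACDE\n>b\nACDF\n"),
        ("clustal", "CLUSTAL W (1.82) multiple sequence alignment\n\n"
                    "a   ACDE\nb   ACDF\n"),
        ("stockholm", "# STOCKHOLM 1.0\na ACDE\nb ACDF\n//\n"),
    ])
    def test_readers(self, tmp_path, fmt, text):
        p = tmp_path / f"aln.{fmt}"
        p.write_text(text)
        msa = Msa.read(p, fmt)
        assert msa.rows == ["ACDE", "ACDF"]


class TestConservation:
    def test_fully_conserved_column_has_max_raw_score(self):
        msa, _ = planted_msa(0)
        prof = M.conservation_profile(msa)
        assert int(np.nanargmax(prof.raw)) == 45

    def test_rescaled_minimum_exactly_zero(self):
        for seed in range(3):
            msa, _ = planted_msa(seed)
            prof = M.conservation_profile(msa)
            assert np.nanmin(prof.rescaled) == 0.0

    def test_uniform_random_column_scores_near_zero(self):
        # relative entropy of a uniform 20-letter column vs background is
        # bounded by the background's deviation from uniform plus sampling
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list(M.BLOSUM62_BACKGROUND), 5))
                for _ in range(2000)]
        msa = Msa(ids=[str(i) for i in range(2000)], rows=rows)
        prof = M.conservation_profile(msa)
        uniform_vs_bg = sum(0.05 * np.log2(0.05 / p / sum(
            M.BLOSUM62_BACKGROUND.values()))
            for p in M.BLOSUM62_BACKGROUND.values())
        assert prof.raw.max() < uniform_vs_bg + 0.25

    def test_row_order_permutation_invariance(self):
        msa, _ = planted_msa(1)
        perm = np.random.default_rng(0).permutation(msa.n_seqs)
        shuffled = Msa(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm])
        a = M.conservation_profile(msa)
        b = M.conservation_profile(shuffled)
        assert np.allclose(a.raw, b.raw, atol=1e-9, equal_nan=True)

    def test_all_gap_column_flagged(self):
        msa = Msa(ids=["a", "b", "c"], rows=["A-C", "A-C", "A-D"])
        prof = M.conservation_profile(msa)
        assert prof.undefined == [1]
        assert np.isnan(prof.raw[1])


class TestCoupling:
    def test_perfect_binary_coupling_is_one_bit(self):
        col_a = ["K"] * 50 + ["E"] * 50
        col_b = ["D"] * 50 + ["R"] * 50
        assert M.pair_mutual_information(col_a, col_b) == pytest.approx(1.0)

    def test_mi_nonnegative_symmetric_zero_diagonal(self):
        msa, _ = planted_msa(2, n=100, length=30, n_pairs=3)
        cr = M.coupling_matrix(msa)
        assert np.all(cr.mi >= -1e-12)
        assert np.allclose(cr.mi, cr.mi.T)
        assert np.allclose(np.diag(cr.mi), 0.0)
        assert np.allclose(cr.mi_apc, cr.mi_apc.T)
        assert np.all(cr.ec_strength >= 0.0)

    def test_planted_pairs_rank_top(self):
        msa, truth = planted_msa(4)
        cr = M.coupling_matrix(msa)
        top15 = {frozenset(p[:2]) for p in cr.top_pairs(15)}
        assert all(frozenset(p) <= set().union(*top15) or frozenset(p) in top15
                   for p in truth.coupled_pairs)
        assert {frozenset(p) for p in truth.coupled_pairs} <= top15

    def test_independent_columns_below_permutation_null(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACDEFGHIKL"), 20)) for _ in range(150)]
        msa = Msa(ids=[str(i) for i in range(150)], rows=rows)
        cr = M.coupling_matrix(msa)
        observed_max = cr.mi_apc[np.triu_indices(len(cr.columns), 1)].max()
        # permutation null: break any residual pairing by shuffling one column
        null = []
        arr = msa.array()
        for rep in range(20):
            perm = rng.permutation(150)
            shuf = arr.copy()
            shuf[:, 7] = arr[perm, 7]
            m2 = Msa(ids=msa.ids, rows=["".join(r) for r in shuf])
            c2 = M.coupling_matrix(m2)
            null.append(c2.mi_apc[7, :].max())
        assert observed_max < np.quantile(null, 0.99) + 0.05

    def test_mostly_gapped_columns_excluded(self):
        rows = ["AC-E" if i % 3 else "ACDE" for i in range(60)]
        msa = Msa(ids=[str(i) for i in range(60)], rows=rows)
        cr = M.coupling_matrix(msa)
        assert 2 in cr.excluded
        assert 2 not in cr.columns

    def test_window_requires_reference_map(self):
        msa, _ = planted_msa(5, n=60, length=20, n_pairs=2)
        with pytest.raises(M.MsaError):
            M.coupling_matrix(msa, window=(868, 880))


class TestTopFraction:
    def test_56_of_561(self):
        scores = {i: float(1000 - i) for i in range(1, 562)}
        assert len(M.top_fraction(scores, 0.10)) == 56

    def test_floor_of_small_sets(self):
        scores = {i: float(i) for i in range(1, 11)}
        assert M.top_fraction(scores, 0.10) == {10}

    def test_ties_broken_by_lower_residue_number(self):
        scores = {i: 1.0 for i in range(1, 21)}
        assert M.top_fraction(scores, 0.25) == {1, 2, 3, 4, 5}

    def test_invalid_inputs(self):
        with pytest.raises(M.MsaError):
            M.top_fraction({}, 0.1)
        with pytest.raises(M.MsaError):
            M.top_fraction({1: 1.0}, 0.0)

    @given(st.integers(5, 200), st.floats(0.01, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_selection_size_property(self, n, fraction):
        scores = {i: float((i * 37) % 13) for i in range(1, n + 1)}
        assert len(M.top_fraction(scores, fraction)) == int(np.floor(fraction * n))


def exact_hypergeom_tail(k, N, K, n):
    """P(X >= k) by direct combinatorial summation."""
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) \
        / comb(N, n)


class TestEnrichment:
    def test_full_overlap_minimal_tail(self):
        out = M.contact_enrichment(set(range(1, 18)), set(range(1, 18)), 561)
        assert out["overlap"] == 17
        assert out["p_tail"] == pytest.approx(
            exact_hypergeom_tail(17, 561, 17, 17), rel=1e-9)

    def test_disjoint_sets_tail_is_one(self):
        out = M.contact_enrichment(set(range(1, 57)), set(range(100, 117)), 561)
        assert out["overlap"] == 0
        assert out["p_tail"] == pytest.approx(1.0)

    def test_matches_exact_combinatorial_oracle(self):
        # 14 of 17 contact residues inside a 56-residue top set of 561
        selected = set(range(1, 57))
        contacts = set(range(43, 57)) | {100, 200, 300}
        out = M.contact_enrichment(selected, contacts, 561)
        assert out["overlap"] == 14
        assert out["p_tail"] == pytest.approx(
            exact_hypergeom_tail(14, 561, 17, 56), rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(M.MsaError):
            M.contact_enrichment({0}, {5}, 561)
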