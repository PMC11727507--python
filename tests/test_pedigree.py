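import logging

import numpy as np
import pandas as pd
import pytest

import pedload as pl
from pedload.pedigree import mendelian_sampling_variance_from_parents

from _oracles import gene_drop_partials
from conftest import small_sim_config


# ---------------------------------------------------------------------------
# Reading and ordering
# ---------------------------------------------------------------------------

class TestReadPedigree:
    def test_founders_only(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("1 0 0\n2 0 0\n")
        ped = pl.read_pedigree(p)
        assert ped.n == 2
        assert ped.is_founder().all()

    def test_sort_idempotence(self, tmp_path):
        """A file listing offspring before parents reads to the same pedigree."""
        sorted_file = tmp_path / "a.txt"
        sorted_file.write_text("1 0 0\n2 0 0\n3 1 2\n")
        shuffled = tmp_path / "b.txt"
        shuffled.write_text("3 1 2\n1 0 0\n2 0 0\n")
        pa = pl.read_pedigree(sorted_file)
        pb = pl.read_pedigree(shuffled)
        assert np.array_equal(pa.ids, pb.ids)
        assert np.array_equal(pa.sire, pb.sire)
        assert np.array_equal(pa.dam, pb.dam)

    def test_undefined_parent_becomes_founder(self, tmp_path, caplog):
        p = tmp_path / "ped.txt"
        p.write_text("1 0 0\n2 0 0\n3 1 9\n")
        with caplog.at_level(logging.WARNING, logger="pedload"):
            ped = pl.read_pedigree(p)
        assert ped.n == 4
        assert 9 in ped.ids
        assert ped.is_founder()[ped.index_of(9)]
        assert any("founder" in r.message for r in caplog.records)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("1 0 0\n1 0 0\n")
        with pytest.raises(ValueError, match="duplicate"):
            pl.read_pedigree(p)

    def test_cycle_detected_and_named(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("1 0 0\n2 3 1\n3 2 1\n")
        with pytest.raises(ValueError, match="cycle"):
            pl.read_pedigree(p)

    def test_header_and_comma_delimiter(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("animal,sire,dam\n1,0,0\n2,0,0\n3,1,2\n")
        ped = pl.read_pedigree(p)
        assert ped.n == 3

    def test_selfing_accepted_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pedload"):
            ped = pl.pedigree_from_arrays([1, 2], [0, 1], [0, 1])
        assert ped.n == 2
        assert any("selfing" in r.message for r in caplog.records)

    def test_sex_role_conflict_rejected(self):
        # animal 1 used as sire of 3 and dam of 4, with sex codes supplied
        with pytest.raises(ValueError, match="both sire and dam"):
            pl.pedigree_from_arrays(
                [1, 2, 3, 4], [0, 0, 1, 2], [0, 0, 2, 1],
                year=[0, 0, 1, 1], sex=["M", "F", "F", "F"],
            )

    def test_roundtrip_write_read(self, tmp_path, mother_son_ped):
        out = tmp_path / "ped.txt"
        pl.write_pedigree(mother_son_ped, out)
        again = pl.read_pedigree(out)
        assert np.array_equal(again.ids, mother_son_ped.ids)
        assert np.array_equal(again.sire, mother_son_ped.sire)


# ---------------------------------------------------------------------------
# Inbreeding coefficients
# ---------------------------------------------------------------------------

class TestInbreeding:
    def test_founders_zero(self):
        ped = pl.pedigree_from_arrays([1, 2], [0, 0], [0, 0])
        assert (pl.compute_inbreeding(ped) == 0).all()

    def test_dam_son_mating(self, mother_son_ped):
        F = pl.compute_inbreeding(mother_son_ped)
        assert F[4] == pytest.approx(0.25, abs=0)

    def test_full_sib_offspring(self, full_sib_ped):
        F = pl.compute_inbreeding(full_sib_ped)
        assert F[5] == pytest.approx(0.25, abs=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_tabular_and_recursive_agree(self, seed):
        ped = pl.simulate_pedigree(small_sim_config(seed=seed))
        Ft = pl.compute_inbreeding(ped, method="tabular")
        Fr = pl.compute_inbreeding(ped, method="recursive")
        assert np.abs(Ft.to_numpy() - Fr.to_numpy()).max() < 1e-12

    def test_unrelated_founder_changes_nothing(self, nested_ped):
        """Monotone depth: appending an unrelated founder is a no-op."""
        F0 = pl.compute_inbreeding(nested_ped)
        phi0 = pl.mendelian_variance(nested_ped, F0)
        pf0 = pl.compute_partial_inbreeding(nested_ped, F=F0)
        bigger = pl.pedigree_from_arrays(
            [1, 2, 3, 4, 5, 6, 99],
            [0, 0, 1, 0, 3, 3, 0],
            [0, 0, 2, 0, 4, 5, 0],
        )
        F1 = pl.compute_inbreeding(bigger)
        phi1 = pl.mendelian_variance(bigger, F1)
        pf1 = pl.compute_partial_inbreeding(bigger, F=F1)
        for a in nested_ped.ids:
            assert F1[a] == F0[a]
            assert phi1[a] == phi0[a]
        pd.testing.assert_frame_equal(pf0.to_frame(), pf1.to_frame())


class TestMendelianVariance:
    @pytest.mark.parametrize(
        "fs,fd,expected",
        [
            (0.0, 0.0, 0.5),
            (None, None, 1.0),
            (0.25, None, 0.5 + 0.25 * 0.75),
            (None, 0.25, 0.6875),
            (0.5, 0.25, 0.25 * 0.5 + 0.25 * 0.75),
        ],
    )
    def test_three_cases(self, fs, fd, expected):
        assert mendelian_sampling_variance_from_parents(fs, fd) == pytest.approx(
            expected, abs=1e-15
        )

    def test_table_over_pedigree(self, mother_son_ped):
        F = pl.compute_inbreeding(mother_son_ped)
        phi = pl.mendelian_variance(mother_son_ped, F)
        assert phi[1] == 1.0 and phi[2] == 1.0
        assert phi[3] == 0.5
        assert phi[4] == 0.5  # parents A (F=0) and C (F=0)


# ---------------------------------------------------------------------------
# Partial inbreeding coefficients
# ---------------------------------------------------------------------------

class TestPartialInbreeding:
    def test_dam_son_single_triplet(self, mother_son_ped):
        pf = pl.compute_partial_inbreeding(mother_son_ped)
        df = pf.to_frame()
        assert len(df) == 1
        assert df.iloc[0].tolist() == [4, 1, 0.25]

    def test_full_sibs_split_between_founders(self, full_sib_ped):
        pf = pl.compute_partial_inbreeding(full_sib_ped)
        df = pf.to_frame().set_index("ancestor")["partial_f"]
        assert set(df.index) == {1, 2}
        assert df[1] == pytest.approx(0.125, abs=0)
        assert df[2] == pytest.approx(0.125, abs=0)

    def test_non_founder_ancestor_contributes(self, nested_ped):
        """Inbreeding through A = G1 x G2 splits between A's Mendelian
        sampling and the two deeper founders."""
        pf = pl.compute_partial_inbreeding(nested_ped)
        df = pf.to_frame().set_index("ancestor")["partial_f"]
        assert df[3] == pytest.approx(0.125, abs=0)
        assert df[1] == pytest.approx(0.0625, abs=0)
        assert df[2] == pytest.approx(0.0625, abs=0)
        assert df.sum() == pytest.approx(0.25, abs=1e-15)

    def test_no_inbreeding_empty(self):
        ped = pl.pedigree_from_arrays([1, 2, 3], [0, 0, 1], [0, 0, 2])
        pf = pl.compute_partial_inbreeding(ped)
        assert len(pf) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_closure_and_screening(self, seed):
        ped = pl.simulate_pedigree(small_sim_config(seed=seed))
        F = pl.compute_inbreeding(ped)
        pf = pl.compute_partial_inbreeding(ped, F=F)
        assert np.abs(pf.totals() - F.to_numpy()).max() < 1e-10
        pf_all = pl.compute_partial_inbreeding(ped, F=F, screen=False)
        assert np.array_equal(pf.descendant, pf_all.descendant)
        assert np.array_equal(pf.ancestor, pf_all.ancestor)
        assert np.array_equal(pf.value, pf_all.value)

    def test_gene_dropping_agrees(self, nested_ped):
        """Monte-Carlo IBD tracing reproduces the recursive decomposition."""
        F = pl.compute_inbreeding(nested_ped)
        pf = pl.compute_partial_inbreeding(nested_ped, F=F)
        got = {
            (int(d), int(a)): v
            for d, a, v in zip(
                nested_ped.ids[pf.descendant], nested_ped.ids[pf.ancestor], pf.value
            )
        }
        focal = nested_ped.index_of(6)
        F_hat, parts, se = gene_drop_partials(
            nested_ped.sire, nested_ped.dam, focal, n_rep=200_000, seed=3
        )
        assert abs(F_hat - F[6]) < 3 * np.sqrt(0.25 * 0.75 / 200_000)
        for k, p in parts.items():
            anc_id = int(nested_ped.ids[k])
            assert abs(p - got.get((6, anc_id), 0.0)) < 3 * max(se[k], 1e-4)

    def test_triplet_file_roundtrip(self, tmp_path, nested_ped):
        pf = pl.compute_partial_inbreeding(nested_ped)
        path = tmp_path / "partials.txt"
        pf.write(path)
        header = path.read_text().splitlines()[0]
        assert header.split() == ["descendant", "ancestor", "partial_f"]
        again = pl.PartialInbreeding.read(path, nested_ped)
        assert np.array_equal(again.value, pf.value)


# ---------------------------------------------------------------------------
# Completeness and summaries
# ---------------------------------------------------------------------------

class TestCompleteness:
    def test_ecg_examples(self):
        # founder -> 0; both parents founders -> 1; full grandparental depth -> 2
        ped = pl.pedigree_from_arrays(
            [1, 2, 3, 4, 5, 6, 7],
            [0, 0, 0, 0, 1, 3, 5],
            [0, 0, 0, 0, 2, 4, 6],
        )
        ecg = pl.equivalent_complete_generations(ped)
        assert ecg[1] == 0.0
        assert ecg[5] == 1.0
        assert ecg[7] == 2.0

    def test_one_known_parent(self):
        ped = pl.pedigree_from_arrays([1, 2], [0, 1], [0, 0])
        ecg = pl.equivalent_complete_generations(ped)
        assert ecg[2] == 0.5


class TestSummary:
    def test_no_inbreeding(self):
        ped = pl.pedigree_from_arrays([1, 2, 3], [0, 0, 1], [0, 0, 2])
        F = pl.compute_inbreeding(ped)
        pf = pl.compute_partial_inbreeding(ped, F=F)
        s, per_anc = pl.summarize_inbreeding(F, pf)
        assert s["pct_inbred"] == 0.0
        assert s["n_partial_coefficients"] == 0
        assert per_anc.empty

    def test_dam_son(self, mother_son_ped):
        F = pl.compute_inbreeding(mother_son_ped)
        pf = pl.compute_partial_inbreeding(mother_son_ped, F=F)
        s, per_anc = pl.summarize_inbreeding(F, pf)
        assert s["n_partial_coefficients"] == 1
        assert s["max_partial_f"] == 0.25
        assert s["n_ancestors_involved"] == 1
        assert s["n_founder_ancestors_involved"] == 1
        assert per_anc["n_descendants_inbred"].tolist() == [1]

    def test_full_sibs(self, full_sib_ped):
        F = pl.compute_inbreeding(full_sib_ped)
        pf = pl.compute_partial_inbreeding(full_sib_ped, F=F)
        s, _ = pl.summarize_inbreeding(F, pf)
        assert s["n_partial_coefficients"] == 2
        assert s["n_ancestors_involved"] == 2
        assert s["n_founder_ancestors_involved"] == 2
        assert s["mean_partial_f"] == pytest.approx(0.125)
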