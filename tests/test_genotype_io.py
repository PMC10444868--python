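"""Parsing, writing, subsetting and reference construction."""

import numpy as np
import pytest

from msatyard import (
    GenotypeMatrix,
    GenotypeParseError,
    SimulationSpec,
    build_reference,
    read_genepop,
    read_genepop_populations,
    read_genotype_table,
    simulate_population,
    subset,
    write_genepop,
    write_genotype_table,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenepop:
    def test_minimal_two_digit_file(self, tmp_path):
        p = _write(tmp_path, "min.gen", "title\nL1\npop\na , 0101\nb , 0102\n")
        g = read_genepop(p)
        assert g.individual_ids == ["a", "b"]
        assert g.locus_names == ["L1"]
        assert g.calls.tolist() == [[[1, 1]], [[1, 2]]]

    def test_half_call_coerced_to_missing(self, tmp_path):
        p = _write(tmp_path, "half.gen", "t\nL1\npop\na , 0100\n")
        g = read_genepop(p)
        assert g.calls.tolist() == [[[0, 0]]]
        assert not g.typed_mask.any()

    def test_three_digit_coding(self, tmp_path):
        p = _write(tmp_path, "w3.gen", "t\nL1\npop\na , 141143\n")
        g = read_genepop(p)
        assert g.calls.tolist() == [[[141, 143]]]

    def test_mixed_width_is_error(self, tmp_path):
        p = _write(tmp_path, "bad.gen", "t\nL1,L2\npop\na , 0101 141143\n")
        with pytest.raises(GenotypeParseError, match="width"):
            read_genepop(p)

    def test_ragged_row_error_carries_line_number(self, tmp_path):
        p = _write(tmp_path, "rag.gen", "t\nL1,L2\npop\na , 0101\n")
        with pytest.raises(GenotypeParseError, match="line 4"):
            read_genepop(p)

    def test_missing_pop_line(self, tmp_path):
        p = _write(tmp_path, "nopop.gen", "t\nL1\na , 0101\n")
        with pytest.raises(GenotypeParseError):
            read_genepop(p)

    def test_multi_pop_file_yields_one_matrix_per_block(self, tmp_path):
        p = _write(
            tmp_path, "two.gen",
            "t\nL1\npop\na , 0101\npop\nb , 0202\nc , 0102\n",
        )
        pops = read_genepop_populations(p)
        assert [g.n_individuals for g in pops] == [1, 2]
        with pytest.raises(GenotypeParseError, match="2 populations"):
            read_genepop(p)

    def test_duplicate_ids_are_uniquified(self, tmp_path):
        p = _write(tmp_path, "dup.gen", "t\nL1\npop\nx , 0101\nx , 0102\n")
        g = read_genepop(p)
        assert g.individual_ids == ["x", "x_2"]


class TestGenepopRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_then_read_recovers_matrix(self, tmp_path, seed):
        g = simulate_population(
            SimulationSpec(n_individuals=15, n_loci=5, seed=seed,
                           missing_rate=0.1, label=f"rt{seed}")
        )
        path = tmp_path / "rt.gen"
        write_genepop(g, path)
        g2 = read_genepop(path)
        assert g2.equals(g)

    def test_allele_pair_order_is_insensitive(self):
        a = GenotypeMatrix(["i1"], ["L1"], np.array([[[143, 141]]]))
        b = GenotypeMatrix(["i1"], ["L1"], np.array([[[141, 143]]]))
        assert a.equals(b)


class TestGenotypeMatrixInvariants:
    def test_half_call_rejected_at_construction(self):
        with pytest.raises(ValueError, match="half-called"):
            GenotypeMatrix(["i1"], ["L1"], np.array([[[141, 0]]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix(["a", "a"], ["L1"], np.zeros((2, 1, 2), dtype=int))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix([], ["L1"], np.zeros((0, 1, 2), dtype=int))


class TestGenotypeTable:
    def test_two_column_dialect(self, tmp_path):
        p = _write(tmp_path, "t.csv", "id,LOC.a1,LOC.a2\nw01,141,143\n")
        g = read_genotype_table(p)
        assert g.locus_names == ["LOC"]
        assert g.calls.tolist() == [[[141, 143]]]

    def test_joined_dialect(self, tmp_path):
        p = _write(tmp_path, "t.csv", "id,LOC\nw01,141/143\nw02,NA\n")
        g = read_genotype_table(p)
        assert g.calls.tolist() == [[[141, 143]], [[0, 0]]]

    def test_half_missing_joined_coerced(self, tmp_path):
        p = _write(tmp_path, "t.csv", "id,LOC\nw01,141/0\n")
        g = read_genotype_table(p)
        assert not g.typed_mask.any()

    def test_duplicate_individual_ids_error(self, tmp_path):
        p = _write(tmp_path, "t.csv", "id,LOC\nw01,141/143\nw01,141/141\n")
        with pytest.raises(GenotypeParseError, match="duplicate"):
            read_genotype_table(p)

    def test_non_integer_allele_error(self, tmp_path):
        p = _write(tmp_path, "t.csv", "id,LOC\nw01,14x/143\n")
        with pytest.raises(GenotypeParseError, match="non-integer"):
            read_genotype_table(p)

    @pytest.mark.parametrize("dialect", ["joined", "two_column"])
    def test_table_round_trip(self, tmp_path, dialect, sim_population):
        path = tmp_path / "rt.csv"
        write_genotype_table(sim_population, path, dialect=dialect)
        g2 = read_genotype_table(path)
        assert g2.individual_ids == sim_population.individual_ids
        assert g2.locus_names == sim_population.locus_names
        assert np.array_equal(g2.calls, sim_population.calls)


class TestSubset:
    def test_identity(self, sim_population):
        g = subset(sim_population)
        assert g.equals(sim_population)

    def test_row_subset_keeps_loci(self, sim_population):
        ids = sim_population.individual_ids[:10]
        g = subset(sim_population, individuals=ids)
        assert g.individual_ids == ids
        assert g.locus_names == sim_population.locus_names

    def test_locus_subset_respects_requested_order(self, sim_population):
        want = [sim_population.locus_names[3], sim_population.locus_names[1]]
        g = subset(sim_population, loci=want)
        assert g.locus_names == want

    def test_unknown_names_listed(self, sim_population):
        with pytest.raises(KeyError, match="nope"):
            subset(sim_population, loci=["nope"])


@pytest.fixture(scope="module")
def two_areas():
    g_main = simulate_population(
        SimulationSpec(n_individuals=145, n_loci=8, seed=10, label="slo")
    )
    g_other = simulate_population(
        SimulationSpec(n_individuals=58, n_loci=8, seed=11, label="gk")
    )
    return g_main, g_other


class TestBuildReference:
    def test_subsample_plus_other_pools_134_individuals(self, two_areas):
        g_main, g_other = two_areas
        ref = build_reference(g_main, g_other, n_select=76, seed=5)
        assert ref.genotypes.n_individuals == 134
        assert ref.full_panel_summary.N == 134
        assert ref.loci_used == g_main.locus_names

    def test_full_selection_is_concatenation(self, two_areas):
        g_main, g_other = two_areas
        ref = build_reference(g_main, g_other, n_select=145, seed=1)
        assert ref.genotypes.individual_ids == (
            g_main.individual_ids + g_other.individual_ids
        )

    def test_same_seed_reproduces_selection(self, two_areas):
        g_main, g_other = two_areas
        r1 = build_reference(g_main, g_other, n_select=76, seed=99)
        r2 = build_reference(g_main, g_other, n_select=76, seed=99)
        assert r1.genotypes.equals(r2.genotypes)

    def test_size_always_n_select_plus_other(self, two_areas):
        g_main, g_other = two_areas
        for n_select in (1, 20, 76):
            ref = build_reference(g_main, g_other, n_select=n_select, seed=0)
            assert ref.genotypes.n_individuals == n_select + 58

    def test_locus_mismatch_error(self, two_areas):
        g_main, g_other = two_areas
        trimmed = subset(g_other, loci=g_other.locus_names[:-1])
        with pytest.raises(ValueError, match="panels differ"):
            build_reference(g_main, trimmed, n_select=10, seed=0)

    def test_overdraw_error(self, two_areas):
        g_main, g_other = two_areas
        with pytest.raises(ValueError, match="n_select"):
            build_reference(g_main, g_other, n_select=146, seed=0)
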