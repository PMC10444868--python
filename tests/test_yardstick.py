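"""The calibration engine: shared loci, resampling, ratios, calibrated values."""

import numpy as np
import pytest

from msatyard import (
    PublishedPopulation,
    SimulationSpec,
    build_reference,
    calibrate,
    confidence_interval,
    locus_diversity,
    population_summary,
    resample_indices,
    shared_loci,
    simulate_pair,
    simulate_population,
    subset,
    yardstick_compare,
)


@pytest.fixture(scope="module")
def reference():
    g_main = simulate_population(
        SimulationSpec(n_individuals=100, n_loci=10, alleles_per_locus=8,
                       seed=21, label="refA")
    )
    g_other = simulate_population(
        SimulationSpec(n_individuals=34, n_loci=10, alleles_per_locus=8,
                       seed=22, label="refB")
    )
    return build_reference(g_main, g_other, n_select=66, seed=23, label="ref")


class TestSharedLoci:
    def _pub(self, loci):
        return PublishedPopulation(
            "s", "t", N=30, per_locus={n: {"He": 0.5} for n in loci}
        )

    def test_intersection_in_reference_order(self, reference):
        names = reference.genotypes.locus_names
        target = self._pub([names[3], names[1], "other"])
        assert shared_loci(reference, target, min_shared=1) == [names[1], names[3]]

    def test_identical_panels_return_full_panel(self, reference):
        target = self._pub(reference.genotypes.locus_names)
        assert shared_loci(reference, target) == reference.genotypes.locus_names

    def test_disjoint_panels_error(self, reference):
        with pytest.raises(ValueError, match="no shared markers"):
            shared_loci(reference, self._pub(["X1", "X2"]))

    def test_alias_map_is_explicit_not_fuzzy(self, reference):
        name = reference.genotypes.locus_names[0]
        spaced = name[:1] + " " + name[1:]
        with pytest.raises(ValueError, match="no shared markers"):
            shared_loci(reference, self._pub([spaced]))
        assert shared_loci(
            reference, self._pub([spaced]), aliases={spaced: name}, min_shared=1
        ) == [name]

    def test_below_min_shared_warns_but_proceeds(self, reference):
        names = reference.genotypes.locus_names[:2]
        with pytest.warns(UserWarning, match="shared loci"):
            got = shared_loci(reference, self._pub(names), min_shared=4)
        assert got == names


class TestResampling:
    def test_single_replicate_is_deterministic(self, reference):
        g = reference.genotypes
        d1 = resample_indices(g, g.locus_names, n_sub=20, n_rep=1, seed=9)
        d2 = resample_indices(g, g.locus_names, n_sub=20, n_rep=1, seed=9)
        assert (d1.a[0], d1.he[0], d1.ho[0]) == (d2.a[0], d2.he[0], d2.ho[0])

    def test_bootstrap_consistency_at_full_n(self, reference):
        """At n_sub = N the resampled He mean sits on the point estimate."""
        g = reference.genotypes
        d = resample_indices(g, g.locus_names, n_sub=g.n_individuals,
                             n_rep=600, seed=31)
        point = population_summary(g).He_mean
        # a single resampled estimate has Monte-Carlo se = sd over replicates;
        # the bootstrap mean carries only the usual O(1/n) resampling bias,
        # far inside that spread
        assert abs(d.mean_he - point) < 3 * d.sd("he")

    def test_rarefaction_monotonicity(self, reference):
        """Mean resampled allele count grows with subsample size."""
        g = reference.genotypes
        means = [
            resample_indices(g, g.locus_names, n_sub=n, n_rep=300, seed=40 + n).mean_a
            for n in (5, 10, 20, 40)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_rejects_degenerate_sizes(self, reference):
        g = reference.genotypes
        with pytest.raises(ValueError):
            resample_indices(g, g.locus_names, n_sub=1, n_rep=10, seed=0)
        with pytest.raises(ValueError):
            resample_indices(g, g.locus_names, n_sub=5, n_rep=0, seed=0)


class TestCalibrationArithmetic:
    def test_unit_ratio_recovers_reference(self, reference):
        full = reference.full_panel_summary
        hec, ac = calibrate(1.0, 1.0, full)
        assert hec == full.He_mean and ac == full.A_mean

    def test_scaling(self, reference):
        full = reference.full_panel_summary
        hec, ac = calibrate(1.05, 0.5, full)
        assert hec == pytest.approx(1.05 * full.He_mean)
        assert ac == pytest.approx(0.5 * full.A_mean)

    def test_missing_art_propagates(self, reference):
        _, ac = calibrate(1.0, None, reference.full_panel_summary)
        assert ac is None

    @pytest.mark.parametrize(
        "est,se,lo,hi",
        [(0.5, 0.1, 0.304, 0.696), (0.685, 0.02, 0.6458, 0.7242), (1.0, 0.0, 1.0, 1.0)],
    )
    def test_confidence_interval(self, est, se, lo, hi):
        assert confidence_interval(est, se) == (pytest.approx(lo), pytest.approx(hi))


class TestCompareModes:
    def test_self_comparison_identity(self, reference):
        """Direct self-calibration: Her = Art = 1, calibrated = full-panel values."""
        res = yardstick_compare(reference, reference.genotypes, seed=1)
        full = reference.full_panel_summary
        assert res.mode == "direct" and res.n_replicates == 0
        assert res.her == 1.0 and res.art == 1.0
        assert res.hec == full.He_mean and res.ac == full.A_mean
        assert res.hoc == pytest.approx(full.Ho_mean)

    def test_larger_genotype_side_is_resampled(self, reference):
        half_ids = reference.genotypes.individual_ids[::2]
        target = subset(reference.genotypes, individuals=half_ids)
        res = yardstick_compare(reference, target, n_rep=400, seed=2)
        assert res.mode == "resample_reference"
        assert res.her == pytest.approx(1.0, abs=3 * max(res.her_se, 1e-3))
        assert abs(res.ac - reference.full_panel_summary.A_mean) <= max(
            3 * res.ac_se, 0.4
        )

    def test_published_smaller_resamples_reference(self, reference):
        pub = PublishedPopulation(
            "s", "small", N=30,
            per_locus={n: {"A": 5.0, "He": 0.6, "Ho": 0.55}
                       for n in reference.genotypes.locus_names[:5]},
        )
        res = yardstick_compare(reference, pub, n_rep=200, seed=3)
        assert res.mode == "resample_reference"
        assert res.n_shared == 5

    def test_published_larger_is_compared_directly(self, reference):
        pub = PublishedPopulation(
            "s", "big", N=reference.genotypes.n_individuals + 50,
            per_locus={n: {"A": 6.0, "He": 0.65, "Ho": 0.6}
                       for n in reference.genotypes.locus_names},
        )
        res = yardstick_compare(reference, pub, seed=4)
        assert res.mode == "direct" and res.n_replicates == 0
        ref_shared = population_summary(reference.genotypes).He_mean
        assert res.her == pytest.approx(0.65 / ref_shared)

    def test_published_matching_own_indices_reproduces_genotype_mode(self, reference):
        """Mode (b) with the target's true per-locus indices tracks mode (a)."""
        half = subset(reference.genotypes,
                      individuals=reference.genotypes.individual_ids[::2])
        per_locus = {
            n: {
                "A": float(locus_diversity(half, n).A),
                "He": locus_diversity(half, n).He,
                "Ho": locus_diversity(half, n).Ho,
            }
            for n in half.locus_names
        }
        pub = PublishedPopulation("s", "half-pub", N=half.n_individuals,
                                  per_locus=per_locus)
        res_geno = yardstick_compare(reference, half, n_rep=500, seed=5)
        res_pub = yardstick_compare(reference, pub, n_rep=500, seed=6)
        tol = 3 * (res_geno.her_se + res_pub.her_se)
        assert res_pub.her == pytest.approx(res_geno.her, abs=max(tol, 0.02))

    def test_missing_per_locus_a_flags_ac_absent(self, reference):
        pub = PublishedPopulation(
            "s", "noA", N=20,
            per_locus={n: {"He": 0.6, "Ho": 0.55}
                       for n in reference.genotypes.locus_names[:4]},
        )
        res = yardstick_compare(reference, pub, n_rep=150, seed=7)
        assert res.art is None and res.ac is None
        assert any("allelic richness" in f for f in res.flags)
        assert res.hoc is not None  # Ho/He still derivable

    def test_missing_ho_flags_hoc_absent(self, reference):
        pub = PublishedPopulation(
            "s", "noHo", N=20,
            per_locus={n: {"A": 4.0, "He": 0.6}
                       for n in reference.genotypes.locus_names[:4]},
        )
        res = yardstick_compare(reference, pub, n_rep=150, seed=8)
        assert res.hoc is None
        assert any("Ho/He" in f for f in res.flags)

    def test_hoc_uses_original_full_panel_ratio(self, reference):
        pub = PublishedPopulation(
            "s", "ratio", N=20,
            per_locus={n: {"He": 0.6, "Ho": 0.3}
                       for n in reference.genotypes.locus_names[:4]},
            ho_over_he=0.9,  # explicit original-data ratio wins
        )
        res = yardstick_compare(reference, pub, n_rep=150, seed=9)
        assert res.hoc == pytest.approx(res.hec * 0.9)


class TestResultInvariants:
    def test_scale_consistency_holds_exactly(self, reference):
        """Hec / He_ref_full = Her and Ac / A_ref_full = Art by construction."""
        full = reference.full_panel_summary
        for seed in (11, 12, 13):
            pub = PublishedPopulation(
                "s", f"t{seed}", N=25 + seed,
                per_locus={n: {"A": 4.0 + seed / 10, "He": 0.55, "Ho": 0.5}
                           for n in reference.genotypes.locus_names[: 4 + seed % 3]},
            )
            res = yardstick_compare(reference, pub, n_rep=100, seed=seed)
            assert res.hec / full.He_mean == pytest.approx(res.her, rel=1e-12)
            assert res.ac / full.A_mean == pytest.approx(res.art, rel=1e-12)
            lo, hi = res.ci("hec")
            assert lo <= res.hec <= hi

    def test_identical_seeds_give_bit_identical_results(self, reference):
        half = subset(reference.genotypes,
                      individuals=reference.genotypes.individual_ids[:40])
        r1 = yardstick_compare(reference, half, n_rep=120, seed=99)
        r2 = yardstick_compare(reference, half, n_rep=120, seed=99)
        assert r1.to_dict() == r2.to_dict()

    def test_parameter_recovery_improves_with_shared_loci(self):
        """Same frequency process on both sides: Hec recovers the truth,
        more precisely as the shared panel grows."""
        widths = {}
        for k in (4, 8, 17):
            ses = []
            for trial in range(6):
                spec = SimulationSpec(
                    n_individuals=60, n_loci=1, alleles_per_locus=8,
                    seed=1000 * k + trial, label=f"pr{k}_{trial}",
                )
                g1, g2, shared = simulate_pair(spec, n_shared=k, n_extra_each=3,
                                               n_individuals_2=40)
                ref = build_reference(
                    subset(g1, individuals=g1.individual_ids[:30]),
                    subset(g1, individuals=g1.individual_ids[30:]),
                    n_select=30, seed=trial, label="ref",
                )
                res = yardstick_compare(ref, g2, n_rep=150, seed=trial)
                truth = population_summary(g2).He_mean
                assert abs(res.hec - truth) < 3 * max(res.hec_se, 0.02) + 0.05
                ses.append(res.hec_se)
            widths[k] = float(np.mean(ses))
        assert widths[17] < widths[4]
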