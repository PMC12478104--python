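"""Generator determinism, planted-effect structure, and round trips."""

import numpy as np
import pytest
from scipy import stats

from amyloidscan.counts import CountTable
from amyloidscan.genotyping import build_count_table
from amyloidscan.reference import VariantId
from amyloidscan.synthetic import (
    CHARGED,
    DEFAULT_APR_REGIONS,
    SelectionDesign,
    emit_reads,
    per_position_mean_truth,
    simulate_ccrit_series,
    simulate_counts,
    simulate_ground_truth,
    simulate_kinetic_trace,
    simulate_stability_profiles,
)
from amyloidscan.thermokinetics import fit_ccrit, half_time


class TestGroundTruth:
    def test_wt_fitness_is_zero(self, truth):
        assert truth.true_fitness[VariantId.wildtype()] == 0.0

    def test_deterministic_given_seed(self, ref):
        a = simulate_ground_truth(ref, seed=3)
        b = simulate_ground_truth(ref, seed=3)
        assert a.true_fitness == b.true_fitness
        assert a.true_survival_midpoint == b.true_survival_midpoint

    def test_midpoints_strictly_increase_with_fitness(self, truth):
        pairs = sorted(
            (f, truth.true_survival_midpoint[v])
            for v, f in truth.true_fitness.items()
        )
        fit, mid = zip(*pairs)
        assert all(m2 > m1 for (f1, m1), (f2, m2) in zip(pairs, pairs[1:]) if f2 > f1)

    def test_apr_charged_substitutions_score_higher(self, ref, truth):
        """Charged residues relieve aggregation inside APRs specifically."""
        in_apr = set()
        for start, end in DEFAULT_APR_REGIONS:
            in_apr.update(range(start, end + 1))
        apr, outside = [], []
        for v, f in truth.true_fitness.items():
            if v.is_wildtype or v.mut_aa not in CHARGED:
                continue
            (apr if v.position in in_apr else outside).append(f)
        assert np.mean(apr) > np.mean(outside)

    def test_fitness_bounded(self, truth):
        vals = truth.fitness_array()
        assert vals.min() >= -4.5 and vals.max() <= 4.5

    @pytest.mark.parametrize(
        "regions", [((0, 5),), ((40, 50),), ((5, 3),), ((1, 10), (8, 20))]
    )
    def test_bad_apr_regions_rejected(self, ref, regions):
        with pytest.raises(ValueError):
            simulate_ground_truth(ref, seed=0, apr_regions=regions)


class TestCounts:
    def test_read_depth_conserved_per_condition(self, truth, small_design):
        counts = simulate_counts(truth, small_design)
        assert (counts.totals() == small_design.read_depth).all()

    def test_deterministic(self, truth, small_design):
        a = simulate_counts(truth, small_design, seed=9)
        b = simulate_counts(truth, small_design, seed=9)
        assert a.df.equals(b.df)

    def test_no_dropout_all_present_unselected(self, truth):
        design = SelectionDesign(read_depth=30_000, n_replicates=1)
        counts = simulate_counts(truth, design, library_dropout=0.0)
        at_zero = counts.variant_counts(0.0, 1)
        assert (at_zero > 0).sum() == 799

    def test_dropout_removes_fraction_everywhere(self, truth):
        design = SelectionDesign(read_depth=30_000, n_replicates=1)
        counts = simulate_counts(truth, design, library_dropout=0.1)
        per_variant = counts.df.groupby("variant")["count"].sum()
        n_absent = 799 - (per_variant > 0).sum()
        assert n_absent == round(0.1 * 798)

    def test_doomed_variant_absent_at_top_concentration(self, ref):
        """A midpoint far below the lowest dose leaves ~zero survivors at 100."""
        truth = simulate_ground_truth(ref, seed=2)
        worst = min(truth.true_survival_midpoint, key=truth.true_survival_midpoint.get)
        assert truth.true_survival_midpoint[worst] < 6.25
        design = SelectionDesign(read_depth=50_000, n_replicates=1)
        counts = simulate_counts(truth, design, seed=4)
        assert counts.variant_counts(100.0, 1).get(worst.label, 0) == 0

    def test_unselected_frequencies_converge_to_library(self, truth):
        """Law of large numbers: c=0 sampling reproduces the library."""
        n = len(truth.variants)
        rng = np.random.default_rng(0)
        f0 = rng.dirichlet(np.full(n, 50.0))
        design = SelectionDesign(
            concentrations=(0.0,), n_replicates=1, read_depth=1_000_000
        )
        counts = simulate_counts(truth, design, library_freq=f0, seed=1)
        emp = (
            counts.variant_counts(0.0, 1)
            .reindex([v.label for v in truth.variants], fill_value=0)
            .to_numpy()
            / design.read_depth
        )
        total_variation = 0.5 * np.abs(emp - f0).sum()
        assert total_variation < 0.015


class TestDesignValidation:
    def test_concentration_zero_required(self):
        with pytest.raises(ValueError):
            SelectionDesign(concentrations=(10.0, 20.0))

    def test_ascending_required(self):
        with pytest.raises(ValueError):
            SelectionDesign(concentrations=(0.0, 50.0, 25.0))

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            SelectionDesign(per_base_error=1.0)

    def test_yaml_round_trip(self, tmp_path):
        d = SelectionDesign(read_depth=123, per_base_error=0.002)
        d.to_yaml(tmp_path / "d.yaml")
        assert SelectionDesign.from_yaml(tmp_path / "d.yaml") == d


class TestReads:
    def test_error_free_round_trip(self, ref, truth, small_design, tmp_path):
        counts = simulate_counts(truth, small_design, seed=5)
        files = emit_reads(counts, ref, small_design, tmp_path, seed=6)
        recovered = build_count_table(files, ref)
        a = counts.df.query("count > 0").set_index(
            ["variant", "concentration", "replicate"]
        )["count"]
        b = recovered.df.query("count > 0").set_index(
            ["variant", "concentration", "replicate"]
        )["count"]
        assert a.sort_index().equals(b.sort_index())

    def test_deterministic_bytes(self, ref, truth, tmp_path):
        design = SelectionDesign(
            concentrations=(0.0, 25.0), n_replicates=1, read_depth=500,
            per_base_error=0.01,
        )
        counts = simulate_counts(truth, design, seed=5)
        fa = emit_reads(counts, ref, design, tmp_path / "a", seed=8)
        fb = emit_reads(counts, ref, design, tmp_path / "b", seed=8)
        for key in fa:
            assert fa[key].read_bytes() == fb[key].read_bytes()

    def test_empty_counts_give_empty_valid_fastq(self, ref, tmp_path):
        design = SelectionDesign(concentrations=(0.0,), n_replicates=1, read_depth=10)
        empty = CountTable.from_mapping(
            {(VariantId.wildtype(), 0.0, 1): 0}
        )
        files = emit_reads(empty, ref, design, tmp_path, seed=0)
        from Bio import SeqIO

        assert list(SeqIO.parse(str(files[(0.0, 1)]), "fastq")) == []


class TestStabilityProfiles:
    def test_noiseless_profiles_track_inverted_fitness(self, ref, truth):
        profiles = simulate_stability_profiles(truth, ref, n_structures=4,
                                               noise_sd=0.0, seed=1)
        target = -per_position_mean_truth(truth, ref)
        for p in profiles:
            r = stats.pearsonr(p.dg, target).statistic
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_structure_ids_distinct(self, ref, truth):
        profiles = simulate_stability_profiles(truth, ref, n_structures=21, seed=2)
        assert len({p.structure_id for p in profiles}) == 21

    def test_overwhelming_noise_destroys_correlation(self, ref, truth):
        """At noise >= 10x the signal sd the profile is uninformative."""
        target = -per_position_mean_truth(truth, ref)
        signal_sd = float(np.std(target))
        rs = []
        for seed in range(100):
            (p,) = simulate_stability_profiles(
                truth, ref, n_structures=1, noise_sd=10 * signal_sd, seed=seed
            )
            rs.append(abs(stats.pearsonr(p.dg, target).statistic))
        assert np.median(rs) < 0.3

    def test_deterministic(self, ref, truth):
        a = simulate_stability_profiles(truth, ref, seed=3)
        b = simulate_stability_profiles(truth, ref, seed=3)
        assert all(np.array_equal(x.dg, y.dg) for x, y in zip(a, b))


class TestKineticAndCcritTraces:
    def test_initial_condition_and_plateau(self):
        t = np.linspace(0.0, 200.0, 50)
        trace = simulate_kinetic_trace(0.5, 2.0, t_grid=t, noise_sd=0.0)
        assert trace.y[0] == 0.0
        assert trace.y[-1] == pytest.approx(1.0, abs=1e-9)

    def test_doubling_kappa_shortens_half_time(self):
        assert half_time(0.5, 4.0) < half_time(0.5, 2.0)

    def test_ccrit_noiseless_values(self):
        series = simulate_ccrit_series(1.0, 1.0, [2.0, 3.0, 4.0], noise_sd=0.0)
        assert np.allclose(series.signal, [1.0, 2.0, 3.0])

    def test_all_below_ccrit_gives_zero_signal(self):
        series = simulate_ccrit_series(5.0, 2.0, [1.0, 2.0, 3.0], noise_sd=0.0)
        assert np.allclose(series.signal, 0.0)

    def test_noiseless_series_round_trips_through_fit(self):
        series = simulate_ccrit_series(0.08, 3.0, [0.5, 1.0, 2.0, 4.0, 8.0],
                                       noise_sd=0.0)
        fit = fit_ccrit(series, n_boot=50)
        assert fit.c_crit == pytest.approx(0.08, abs=1e-9)


class TestMonotoneCoupling:
    def test_rank_recovery_improves_with_depth(self, ref):
        """Deeper sequencing recovers the planted ranking more faithfully."""
        from amyloidscan.scoring import score_fitness

        truth = simulate_ground_truth(ref, seed=13)
        tf = {v.label: f for v, f in truth.true_fitness.items()}
        rhos = []
        for depth in (500, 5_000, 50_000):
            design = SelectionDesign(read_depth=depth, n_replicates=1)
            counts = simulate_counts(truth, design, seed=14)
            tab = score_fitness(counts, ref)
            tab["truth"] = tab["variant"].map(tf)
            ok = tab["mean_fitness"].notna()
            rhos.append(
                stats.spearmanr(tab.loc[ok, "truth"], tab.loc[ok, "mean_fitness"])
                .statistic
            )
        assert rhos[0] < rhos[1] < rhos[2]
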