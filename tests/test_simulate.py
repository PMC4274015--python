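"""Serial-transfer simulator: regimes, mutation, PCR, bottleneck, pipeline."""

import numpy as np
import pytest

from olisim import (
    MutationModel,
    OliPopulation,
    SimConfig,
    bottleneck_sample,
    digest_population,
    extend_by_self_priming,
    make_regime,
    mutate_seq,
    pcr_amplify,
    run_experiment,
    self_priming_step,
    sequence_population,
)
from olisim.simulate import REGIME_NAMES, scaled_config

ZERO_MUT = MutationModel(sub_rate=0.0, indel_rate=0.0)


class TestRegimes:
    def test_control_is_constant(self):
        assert make_regime("control").temps == (55.0,) * 11

    def test_slow_rises_by_one_and_a_half_each_transfer(self):
        temps = make_regime("slow").temps
        assert temps[0] == 55.0 and temps[-1] == 70.0
        assert all(b - a == 1.5 for a, b in zip(temps, temps[1:]))

    @pytest.mark.parametrize("name", ["sudden", "intermediate", "slow"])
    def test_change_regimes_share_total_increase(self, name):
        temps = make_regime(name).temps
        assert temps[-1] == 70.0
        assert sum(b - a for a, b in zip(temps, temps[1:])) == pytest.approx(15.0)

    def test_step_counts(self):
        def steps(name):
            t = make_regime(name).temps
            return sum(1 for a, b in zip(t, t[1:]) if b > a)

        assert steps("sudden") == 1
        assert steps("intermediate") == 5
        assert steps("slow") == 10

    def test_unknown_regime(self):
        with pytest.raises(ValueError):
            make_regime("glacial")


class TestMutateSeq:
    def test_zero_rates_identity(self, ancestor, rng):
        assert mutate_seq(ancestor, ZERO_MUT, rng) == ancestor

    def test_saturating_spectrum_to_a(self, rng):
        to_a = MutationModel(
            sub_rate=1.0,
            indel_rate=0.0,
            spectrum=(
                (0.0, 1 / 3, 1 / 3, 1 / 3),
                (1.0, 0.0, 0.0, 0.0),
                (1.0, 0.0, 0.0, 0.0),
                (1.0, 0.0, 0.0, 0.0),
            ),
        )
        assert mutate_seq("GGG", to_a, rng) == "AAA"

    def test_mean_substitutions_match_binomial_expectation(self, rng):
        model = MutationModel(sub_rate=0.008, indel_rate=0.0)
        seq = "ACGT" * 250  # 1000 bases, expectation 8 per copy
        diffs = []
        for _ in range(2000):
            mut = mutate_seq(seq, model, rng)
            diffs.append(sum(a != b for a, b in zip(seq, mut)))
        # SE of the mean ~ sqrt(8/2000) ~ 0.063; allow ~4 sigma
        assert np.mean(diffs) == pytest.approx(8.0, abs=0.3)

    def test_indels_change_length(self, rng):
        model = MutationModel(sub_rate=0.0, indel_rate=0.2)
        lengths = {len(mutate_seq("ACGT" * 25, model, rng)) for _ in range(50)}
        assert lengths != {100}

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            MutationModel(spectrum=((0.5, 0.5, 0, 0),) * 4)


class TestSelfPriming:
    def test_cold_temperature_extends_everything_stable(self, ancestor, rng):
        pop = OliPopulation.founding(500)
        out = self_priming_step(pop, 20.0, rng=rng)  # deep below the midpoint
        assert out.extended_fraction > 0.99

    def test_stemless_population_never_extends(self, rng):
        pop = OliPopulation(counts={("ACACACAC" * 5, False): 300})
        out = self_priming_step(pop, 45.0, rng=rng)
        assert out.extended_copies == 0

    def test_hot_extends_fewer_than_warm(self, ancestor):
        fracs = {}
        for temp in (55.0, 70.0):
            rng = np.random.default_rng(11)
            out = self_priming_step(OliPopulation.founding(20_000), temp, rng=rng)
            fracs[temp] = out.extended_fraction
        assert fracs[70.0] < fracs[55.0]

    def test_total_copies_conserved(self, rng):
        pop = OliPopulation.founding(1234)
        assert self_priming_step(pop, 55.0, rng=rng).total_copies == 1234


class TestPcrAmplify:
    def test_pure_exponential_doubling(self, extended, rng):
        pop = OliPopulation(counts={(extended, True): 1})
        out, curve = pcr_amplify(pop, 10, 10_000, ZERO_MUT, rng)
        assert out.total_copies == 1024
        assert list(curve.totals) == [2.0 ** c for c in range(11)]

    def test_pure_linear_growth(self, ancestor, rng):
        pop = OliPopulation(counts={(ancestor, False): 1})
        out, curve = pcr_amplify(pop, 10, 10_000, ZERO_MUT, rng)
        assert out.total_copies == 11
        assert list(curve.totals) == list(range(1, 12))

    def test_primer_pool_caps_growth(self, extended, rng):
        pop = OliPopulation(counts={(extended, True): 1})
        out, curve = pcr_amplify(pop, 20, 50, ZERO_MUT, rng)  # pool = 100 strands
        assert out.total_copies <= 101
        assert curve.totals[-1] == curve.totals[-2]  # plateau reached

    def test_growth_curve_non_decreasing(self, extended, ancestor, rng):
        pop = OliPopulation(counts={(extended, True): 40, (ancestor, False): 60})
        _, curve = pcr_amplify(pop, 25, 5_000, MutationModel(), rng)
        assert np.all(np.diff(curve.totals) >= 0)

    def test_mutants_in_primer_footprint_drop_to_linear(self, extended, rng):
        """With a mutation model that always hits the 5' footprint, every new
        copy loses exponential growth immediately."""
        always_head = MutationModel(
            sub_rate=1.0,
            indel_rate=0.0,
            spectrum=(
                (0.0, 1.0, 0.0, 0.0),
                (1.0, 0.0, 0.0, 0.0),
                (1.0, 0.0, 0.0, 0.0),
                (1.0, 0.0, 0.0, 0.0),
            ),
        )
        pop = OliPopulation(counts={(extended, True): 10})
        out, _ = pcr_amplify(pop, 3, 10_000, always_head, rng)
        # originals stay exponential: 10 -> 20 -> 40 -> 80; all new copies are
        # saturated mutants and none keeps both footprints
        assert sum(c for (s, ext), c in out.counts.items() if ext) == 10


class TestDigestAndBottleneck:
    def test_digestion_restores_unit_length_and_conserves_copies(self, ancestor, extended):
        pop = OliPopulation(counts={(extended, True): 120, (ancestor, False): 30})
        out = digest_population(pop)
        assert out.total_copies == 150
        assert set(s for (s, _), _ in out.counts.items()) == {ancestor}
        assert out.extended_copies == 0

    def test_site_free_survivor_stays_extended(self):
        survivor = "ATGGATCCATTTAAACCCGGGATATATATATCCATGGATCC"
        pop = OliPopulation(counts={(survivor, True): 5})
        out = digest_population(pop)
        assert out.counts == {(survivor, True): 5}

    def test_bottleneck_identity_when_small_population(self, ancestor, rng):
        pop = OliPopulation(counts={(ancestor, False): 90})
        assert bottleneck_sample(pop, 100, rng).counts == pop.counts

    def test_bottleneck_single_genotype(self, ancestor, rng):
        pop = OliPopulation(counts={(ancestor, False): 10_000})
        out = bottleneck_sample(pop, 250, rng)
        assert out.counts == {(ancestor, False): 250}

    def test_bottleneck_unbiased(self, ancestor, extended):
        fractions = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pop = OliPopulation(counts={(ancestor, False): 5000, (extended, True): 5000})
            out = bottleneck_sample(pop, 1000, rng)
            fractions.append(out.counts.get((extended, True), 0) / 1000)
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.02)

    def test_bottleneck_empty_population_raises(self, rng):
        with pytest.raises(ValueError):
            bottleneck_sample(OliPopulation(), 10, rng)


class TestSequencing:
    def test_single_genotype_reads_identical(self, ancestor, rng):
        pop = OliPopulation(counts={(ancestor, False): 50})
        reads = sequence_population(pop, 20, rng=rng, treatment="control", transfer=3)
        assert len(reads) == 20
        assert all(str(r.seq) == ancestor for r in reads)

    def test_headers_carry_metadata(self, ancestor, rng):
        pop = OliPopulation(counts={(ancestor, False): 5})
        (read, *_) = sequence_population(
            pop, 3, rng=rng, treatment="slow", transfer=7, replicate=4
        )
        assert read.id.startswith("slow|t7|r4|")

    def test_depth_exceeding_population_resamples_proportionally(self, ancestor, extended, rng):
        pop = OliPopulation(counts={(ancestor, False): 30, (extended, True): 10})
        reads = sequence_population(pop, 4000, rng=rng)
        frac = sum(str(r.seq) == ancestor for r in reads) / 4000
        assert frac == pytest.approx(0.75, abs=0.05)


class TestRunExperiment:
    def test_zero_mutation_control_keeps_only_ancestor(self, ancestor):
        cfg = scaled_config("control", n_replicates=1, seed=3, mutation=ZERO_MUT)
        result = run_experiment(cfg)
        final = result.final_populations[1]
        assert set(final.genotype_counts()) == {ancestor}

    def test_identical_seeds_give_identical_outputs(self):
        cfg = scaled_config("sudden", n_replicates=1, seed=9, n_transfers=3,
                            sampled_transfers=(1, 3))
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        for key in a.reads:
            assert [str(r.seq) for r in a.reads[key]] == [str(r.seq) for r in b.reads[key]]
        for key in a.curves:
            assert np.array_equal(a.curves[key].totals, b.curves[key].totals)

    def test_totals_respect_primer_budget(self):
        cfg = scaled_config("control", n_replicates=1, seed=2, n_transfers=2,
                            sampled_transfers=(1,))
        result = run_experiment(cfg)
        cap = cfg.founding_copies + 2 * cfg.primer_copies
        for curve in result.curves.values():
            assert curve.totals.max() <= cap
            assert np.all(np.diff(curve.totals) >= 0)

    def test_neutral_genotypes_drift_without_bias(self, ancestor, rng):
        """Two genotypes with identical stems change frequency only through
        bottleneck sampling: the mean change across replicates is ~0."""
        variant = ancestor[:40] + ("A" if ancestor[40] != "A" else "C") + ancestor[41:]
        changes = []
        for seed in range(30):
            g = np.random.default_rng(seed)
            pop = OliPopulation(counts={(ancestor, False): 2000, (variant, False): 2000})
            pop = self_priming_step(pop, 55.0, rng=g)
            pop, _ = pcr_amplify(pop, 12, 20_000, ZERO_MUT, g)
            pop = digest_population(pop)
            pop = bottleneck_sample(pop, 2000, g)
            freq = pop.genotype_counts()[ancestor] / pop.total_copies
            changes.append(freq - 0.5)
        assert np.mean(changes) == pytest.approx(0.0, abs=0.02)

    def test_writes_outputs(self, tmp_path):
        cfg = scaled_config("control", n_replicates=1, seed=5, n_transfers=1,
                            sampled_transfers=(1,))
        run_experiment(cfg, out_dir=tmp_path)
        assert (tmp_path / "growth_curves.csv").exists()
        assert (tmp_path / "manifest.yaml").exists()
        assert list(tmp_path.glob("control_r01_t01.fasta"))
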