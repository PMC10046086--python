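"""Simulator: count laws, spectrum fidelity, determinism, depth tracks."""

import numpy as np
import pytest

from malspectra import (
    MALDesign,
    SimParams,
    mtdna_copy_number,
    sample_snvs,
    simulate_depth_tracks,
    simulate_mal_experiment,
    spectrum_summary,
)
from malspectra.genome import Genome, random_genome
from malspectra.spectra import MutationSpectrum


def _design(generations=1260, reps=4, **kw):
    return MALDesign("S", generations_total=generations, replicate_count=reps, **kw)


class TestDesignValidation:
    def test_generations_must_be_multiple_of_bottlenecks(self):
        MALDesign("S", generations_total=2520, bottleneck_count=120)  # 21 each
        with pytest.raises(ValueError):
            MALDesign("S", generations_total=2521, bottleneck_count=120)

    @pytest.mark.parametrize("kw", [dict(generations_total=0), dict(generations_total=10, replicate_count=0)])
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(ValueError):
            MALDesign("S", **{"generations_total": 10, **kw})


class TestMutationCounts:
    def test_zero_rates_give_empty_truth(self, toy_genome):
        exp = simulate_mal_experiment(
            toy_genome, _design(), SimParams(snv_rate=0.0, indel_rate=0.0, seed=1)
        )
        assert all(len(v) == 0 for v in exp.truth.truth.values())

    def test_poisson_mean_matches_rate_length_generations(self, yeast_scale_genome):
        # E[total] = mu * L * T * replicates = 2.7e-9 * 12.07e6 * 1260 * 4
        mu, T, reps = 2.7e-9, 1260, 4
        L = yeast_scale_genome.compartment_length("nuclear")
        expected = mu * L * T * reps
        totals = []
        for seed in range(200):
            exp = simulate_mal_experiment(
                yeast_scale_genome, _design(T, reps), SimParams(snv_rate=mu, seed=seed)
            )
            totals.append(sum(len(v) for v in exp.truth.truth.values()))
        mean = np.mean(totals)
        # Monte-Carlo 3-sigma band around the Poisson mean
        assert abs(mean - expected) < 3 * np.sqrt(expected / 200)

    def test_uniform_spectrum_recovers_neutral_ts_tv(self, toy_genome):
        snvs = sample_snvs(
            toy_genome, 30_000, MutationSpectrum.uniform(), np.random.default_rng(5)
        )
        ts_tv = spectrum_summary(snvs).ts_tv
        assert ts_tv == pytest.approx(0.5, rel=0.05)

    def test_infinite_sites_no_repeated_positions_within_replicate(self, toy_genome):
        exp = simulate_mal_experiment(
            toy_genome, _design(), SimParams(snv_rate=5e-7, indel_rate=1e-7, seed=3)
        )
        for muts in exp.truth.truth.values():
            sites = [(v.chromosome, v.position) for v in muts]
            assert len(sites) == len(set(sites))


class TestCallerEmulation:
    def test_every_emitted_call_is_truth_ancestor_or_fp(self, toy_genome):
        params = SimParams(
            snv_rate=3e-7, caller_fp_rate=5e-8, caller_fn_rate=0.1,
            ancestor_variant_count=5, seed=9,
        )
        exp = simulate_mal_experiment(toy_genome, _design(), params)
        anc = {v.key for v in exp.truth.ancestor}
        for rep, callers in exp.caller_calls.items():
            truth = {v.key for v in exp.truth.truth[rep]}
            for caller, calls in callers.items():
                fps = {v.key for v in exp.truth.false_positives[(rep, caller)]}
                for c in calls:
                    assert c.key in truth | anc | fps

    def test_ancestor_variants_present_in_all_caller_sets(self, toy_genome):
        params = SimParams(
            snv_rate=1e-7, caller_fn_rate=0.5, ancestor_variant_count=8, seed=2
        )
        exp = simulate_mal_experiment(toy_genome, _design(), params)
        anc = {v.key for v in exp.truth.ancestor}
        assert len(anc) == 8
        for callers in exp.caller_calls.values():
            for calls in callers.values():
                assert anc <= {c.key for c in calls}

    def test_false_negatives_thin_caller_output(self, toy_genome):
        fn = 0.3
        kept = total = 0
        for seed in range(20):
            exp = simulate_mal_experiment(
                toy_genome, _design(),
                SimParams(snv_rate=3e-7, caller_fn_rate=fn, seed=seed),
            )
            for rep, callers in exp.caller_calls.items():
                truth = {v.key for v in exp.truth.truth[rep]}
                total += len(truth)
                kept += len(truth & {c.key for c in callers["callerA"]})
        assert kept / total == pytest.approx(1 - fn, abs=0.03)


class TestDeterminism:
    def test_same_seed_identical_output(self, toy_genome):
        params = SimParams(
            snv_rate=3e-7, indel_rate=5e-8, caller_fp_rate=2e-8,
            caller_fn_rate=0.05, ancestor_variant_count=3, seed=17,
        )
        a = simulate_mal_experiment(toy_genome, _design(), params)
        b = simulate_mal_experiment(toy_genome, _design(), params)
        assert a.caller_calls == b.caller_calls
        assert a.truth.truth == b.truth.truth
        ta = simulate_depth_tracks(toy_genome, params)
        tb = simulate_depth_tracks(toy_genome, params)
        for x, y in zip(ta, tb):
            assert np.array_equal(x.depths, y.depths)


class TestValidation:
    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            Genome({"chr1": ""})

    def test_wrong_spectrum_dimension_rejected(self):
        with pytest.raises(ValueError):
            MutationSpectrum([0.5, 0.5])
        with pytest.raises(ValueError):
            MutationSpectrum(np.full(6, 0.2))  # sums to 1.2

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(snv_rate=-1e-9)


class TestDepthTracks:
    def test_rho0_mito_windows_all_zero(self, toy_genome):
        params = SimParams(snv_rate=0, mito_copy_ratio=0.0, seed=1)
        tracks = simulate_depth_tracks(toy_genome, params)
        mito = next(t for t in tracks if t.chromosome == "chrM")
        assert np.all(mito.depths == 0)
        assert mtdna_copy_number(tracks, "chrM") == 0.0

    def test_noise_off_gives_exact_mean_depth(self, toy_genome):
        params = SimParams(snv_rate=0, mean_depth=88.0, seed=1)
        tracks = simulate_depth_tracks(toy_genome, params, noise=False)
        for t in tracks:
            if t.chromosome != "chrM":
                assert np.all(t.depths == 88.0)

    def test_trisomy_triples_mean_depth(self, toy_genome):
        params = SimParams(
            snv_rate=0, mean_depth=88.0, ploidy_events=(("chrI", 3),), seed=1
        )
        tracks = simulate_depth_tracks(toy_genome, params, noise=False)
        chr1 = next(t for t in tracks if t.chromosome == "chrI")
        assert np.all(chr1.depths == 264.0)  # 3 x 88

    def test_window_larger_than_chromosome_truncates(self):
        genome = random_genome({"tiny": 500}, seed=0)
        tracks = simulate_depth_tracks(
            genome, SimParams(snv_rate=0, seed=0), window_size=1000, noise=False
        )
        (t,) = tracks
        assert len(t) == 1 and t.starts[0] == 0 and t.ends[0] == 500

    def test_negative_binomial_noise_has_configured_dispersion(self, toy_genome):
        params = SimParams(snv_rate=0, mean_depth=88.0, depth_dispersion=2.0, seed=4)
        tracks = simulate_depth_tracks(toy_genome, params, window_size=200)
        depths = np.concatenate(
            [t.depths for t in tracks if t.chromosome != "chrM"]
        )
        assert depths.mean() == pytest.approx(88.0, rel=0.05)
        assert depths.var() / depths.mean() == pytest.approx(2.0, rel=0.25)
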