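"""Selection-round simulator: binding model, thinning, amplification, reads."""

import numpy as np
import pytest

from pdselex.io import FastqRecord
from pdselex.simulate import (
    KdLandscape,
    Pool,
    RoundConfig,
    SelectionCrash,
    amplify,
    avidity_adjusted_kd,
    capture_probability,
    equilibrium_bound_fraction,
    generate_reads,
    mock_mixture_study,
    simulate_campaign,
    simulate_round,
)


def make_pool(kind, ids, counts, templates=None):
    return Pool(kind=kind, ids=list(ids), sequences=list(ids),
                counts=np.asarray(counts, dtype=float), templates=templates)


class TestBindingModel:
    def test_half_saturation(self):
        assert equilibrium_bound_fraction(1e-9, 1e-9) == pytest.approx(0.5)

    def test_zero_concentration(self):
        assert equilibrium_bound_fraction(1e-9, 0.0) == 0.0

    def test_closed_form_value(self):
        # 1e-8 / (1e-8 + 1e-11), evaluated independently
        assert equilibrium_bound_fraction(1e-11, 1e-8) == pytest.approx(
            0.999000999000999, rel=1e-12
        )

    def test_avidity_identity_and_scaling(self):
        assert avidity_adjusted_kd(1e-9, copies=1, urea=False) == 1e-9
        assert avidity_adjusted_kd(1e-9, copies=10, avidity_exponent=1.0) == (
            pytest.approx(1e-10)
        )
        with_urea = avidity_adjusted_kd(1e-9, copies=1, urea=True, urea_penalty=5.0)
        assert with_urea == pytest.approx(5e-9)


class TestCaptureProbability:
    def test_nonbinder_zero_background(self):
        rna = make_pool("rna", ["x"], [100])
        phage = make_pool("protein", ["p"], [100])
        cfg = RoundConfig(background_step1=0.0)
        assert capture_probability("x", phage, KdLandscape(), cfg) == 0.0

    def test_saturated_binder_approaches_one(self):
        phage = make_pool("protein", ["p"], [100])
        landscape = KdLandscape()
        landscape.add("x", "p", 1e7, 1e-7)  # K_D = 1e-14 M
        cfg = RoundConfig(capture_eff_step1=1.0, background_step1=0.0,
                          effective_protein_conc=1e-9, avidity_copies=1)
        p = capture_probability("x", phage, landscape, cfg)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_planted_closed_form(self):
        """capture 0.5 x C/(C+K_D) + background, no washes, monovalent."""
        phage = make_pool("protein", ["p"], [100])
        landscape = KdLandscape()
        landscape.add("x", "p", 1e7, 1e-4)  # K_D = 1e-11 M
        cfg = RoundConfig(capture_eff_step1=0.5, background_step1=1e-4,
                          effective_protein_conc=1e-9, avidity_copies=1,
                          n_washes=0)
        p = capture_probability("x", phage, landscape, cfg)
        assert p == pytest.approx(0.49514950495049503, rel=1e-12)

    def test_unknown_species_rejected(self):
        phage = make_pool("protein", ["p"], [100])
        with pytest.raises(KeyError):
            make_pool("rna", ["x"], [1]).index_of("nope")


class TestSimulateRound:
    def test_all_zero_rates_crash(self):
        rna = make_pool("rna", ["a"], [100])
        phage = make_pool("protein", ["p"], [100])
        cfg = RoundConfig(capture_eff_step1=0.0, capture_eff_step2=0.0,
                          background_step1=0.0, background_step2=0.0)
        result = simulate_round(rna, phage, KdLandscape(), cfg,
                                mode="expectation")
        assert result.crashed
        assert result.captured_rna.total == 0

    def test_expectation_matches_mixture_closed_form(self):
        rna, phage, landscape, cfg = mock_mixture_study(binder_fraction=0.01)
        p_b = capture_probability("Kt", phage, landscape, cfg)
        p_n = capture_probability("dKt", phage, landscape, cfg)
        f = 0.01
        expected = f * p_b / (f * p_b + (1 - f) * p_n)
        result = simulate_round(rna, phage, landscape, cfg, mode="expectation")
        assert result.captured_rna.abundances[0] == pytest.approx(
            expected, rel=1e-14
        )

    def test_stochastic_determinism(self):
        rna, phage, landscape, cfg = mock_mixture_study()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            result = simulate_round(rna, phage, landscape, cfg,
                                    mode="stochastic", rng=rng)
            out.append((result.captured_rna.counts.copy(),
                        result.captured_phage.counts.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_expectation_is_stochastic_mean(self):
        """Expected counts equal the mean over seeds within 3 SE."""
        rna, phage, landscape, cfg = mock_mixture_study(total_rna=10_000,
                                                        total_phage=10_000)
        exp = simulate_round(rna, phage, landscape, cfg, mode="expectation")
        draws = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = simulate_round(rna, phage, landscape, cfg,
                                 mode="stochastic", rng=rng)
            draws.append(res.captured_rna.counts)
        draws = np.array(draws)
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - exp.captured_rna.counts) <= 3 * se + 1e-9)

    def test_more_washes_never_hurt_cognate_enrichment(self):
        """Washing depletes only the nonspecific background, so the cognate
        expected enrichment factor is non-decreasing in wash count."""
        rna, phage, landscape, _ = mock_mixture_study()
        previous = -np.inf
        for washes in (0, 2, 4, 8):
            cfg = RoundConfig(n_washes=washes, background_step1=1e-3,
                              effective_protein_conc=1e-9)
            res = simulate_round(rna, phage, landscape, cfg, mode="expectation")
            ef = res.captured_rna.abundances[0] / 0.01
            assert ef >= previous
            previous = ef

    def test_negative_selection_removes_flagged(self):
        rna = Pool(kind="rna", ids=["a", "sticky"], sequences=["a", "s"],
                   counts=np.array([100.0, 100.0]),
                   bead_binder=np.array([False, True]))
        phage = make_pool("protein", ["p"], [100])
        cfg = RoundConfig(negative_selection=True, background_step1=0.5,
                          n_washes=0)
        res = simulate_round(rna, phage, KdLandscape(), cfg, mode="expectation")
        assert res.captured_rna.counts[1] == 0.0
        assert res.captured_rna.counts[0] > 0.0


class TestAmplify:
    def test_exact_proportional_scaling(self, rng):
        pool = make_pool("rna", ["a", "b"], [30, 70])
        out = amplify(pool, target_total=1000, amplification_noise_sd=0.0,
                      rng=rng)
        np.testing.assert_array_equal(out.counts, [300.0, 700.0])

    def test_single_species_keeps_abundance_one(self, rng):
        pool = make_pool("rna", ["a"], [17])
        out = amplify(pool, 500, 0.5, rng)
        assert out.abundances[0] == 1.0

    def test_abundance_preserved_in_expectation_with_noise(self):
        pool = make_pool("rna", ["a", "b"], [2000, 8000])
        fracs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            out = amplify(pool, 10_000, amplification_noise_sd=0.3, rng=rng)
            fracs.append(out.abundances[0])
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.2) <= 3 * se


class TestGenerateReads:
    def test_error_free_reads_match_template(self, rng):
        pool = make_pool("rna", ["a"], [10], templates=["ACGTACGT"])
        reads = generate_reads(pool, 50, 0.0, "AA", rng)
        assert len(reads) == 50
        assert all(r.sequence == "AAACGTACGT" for r in reads)

    def test_zero_reads(self, rng):
        pool = make_pool("rna", ["a"], [10], templates=["ACGT"])
        assert generate_reads(pool, 0, 0.0, "", rng) == []

    def test_binomial_split(self, rng):
        pool = make_pool("rna", ["a", "b"], [500, 500],
                         templates=["AAAA", "CCCC"])
        reads = generate_reads(pool, 100_000, 0.0, "", rng)
        n_a = sum(r.sequence == "AAAA" for r in reads)
        # within 3 sigma of Binomial(1e5, 0.5)
        assert abs(n_a - 50_000) <= 3 * np.sqrt(100_000 * 0.25)

    def test_error_rate_injects_substitutions(self, rng):
        pool = make_pool("rna", ["a"], [10], templates=["A" * 100])
        reads = generate_reads(pool, 200, 0.05, "", rng)
        n_sub = sum(sum(ch != "A" for ch in r.sequence) for r in reads)
        # 200 * 100 * 0.05 = 1000 expected substitutions
        assert 700 <= n_sub <= 1300


class TestCampaign:
    def _setup(self):
        rna, phage, landscape, cfg = mock_mixture_study()
        from pdselex.simulate import CampaignConfig

        campaign = CampaignConfig(rounds=[cfg])
        return campaign, rna, phage, landscape

    def test_one_round_equals_round_plus_amplify(self):
        campaign, rna, phage, landscape = self._setup()
        result = simulate_campaign(campaign, rna, phage, landscape,
                                   mode="expectation")
        direct = simulate_round(rna, phage, landscape, campaign.rounds[0],
                                mode="expectation")
        amplified = amplify(direct.captured_rna, campaign.rounds[0].rna_input,
                            mode="expectation")
        np.testing.assert_allclose(result.rna_pools[1].counts,
                                   amplified.counts, rtol=1e-12)

    def test_crash_propagates_round_index(self):
        campaign, rna, phage, landscape = self._setup()
        dead = RoundConfig(capture_eff_step1=0.0, capture_eff_step2=0.0,
                           background_step1=0.0, background_step2=0.0)
        campaign.rounds = [campaign.rounds[0], dead]
        rng = np.random.default_rng(5)
        with pytest.raises(SelectionCrash) as err:
            simulate_campaign(campaign, rna, phage, landscape,
                              mode="stochastic", rng=rng)
        assert err.value.round_index == 2

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        from pdselex.io import write_fastq
        from pdselex.simulate import CampaignConfig

        rna, phage, landscape, cfg = mock_mixture_study(total_rna=1000,
                                                        total_phage=1000)
        rna.templates = ["ACGTACGTAC", "TTTTACGTACGTAC"]
        phage.templates = ["GGGCCCAAATTT", "AAACCCGGGTTT"]
        campaign = CampaignConfig(rounds=[cfg], reads_per_round=500,
                                  rna_barcodes=["AACCGGTT", "CCAATTGG"],
                                  protein_barcodes=["AACCGGTT", "CCAATTGG"])
        blobs = []
        for run in range(2):
            result = simulate_campaign(campaign, rna, phage, landscape,
                                       mode="stochastic",
                                       rng=np.random.default_rng(21))
            path = tmp_path / f"run{run}.fastq"
            write_fastq(result.rna_reads[1], path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]
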