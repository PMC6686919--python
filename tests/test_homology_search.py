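"""Scoring, calibration, E-values, filtering and copy counting."""

import math

import numpy as np
import pytest

from reservescan.alphabet import encode, random_protein
from reservescan.errors import (
    CalibrationError,
    IntegrityError,
    InvalidParameterError,
    UncalibratedModelError,
)
from reservescan.homology_search import (
    Hit,
    ScreeningConfig,
    calibrate,
    count_copies,
    evalue_of,
    filter_hits,
    fit_gumbel,
    score_sequence,
)

from oracles import enumerate_viterbi, random_profile


def make_hit(evalue=1e-12, coverage=0.8, protein_id="p1", enzyme_id="ws_dgat",
             model_id=None, proteome_id="P1"):
    return Hit(
        enzyme_id=enzyme_id,
        model_id=model_id or f"{enzyme_id}:denovo",
        proteome_id=proteome_id,
        protein_id=protein_id,
        bit_score=100.0,
        evalue=evalue,
        query_span=(0, 80),
        target_span=(0, 80),
        query_coverage=coverage,
    )


class TestScoreSequence:
    def test_consensus_of_peaked_model_scores_positive_full_span(self, rng):
        model = random_profile(rng, 5)
        # sharpen emissions so the consensus is strongly favoured
        peaked = np.full_like(model.match_emissions, 0.002 / 19)
        for k in range(5):
            peaked[k, np.argmax(model.match_emissions[k])] = 0.998
        model.match_emissions = peaked
        score, qspan, tspan = score_sequence(model, model.consensus)
        assert score > 0
        assert qspan == (0, 5)
        assert tspan == (0, 5)

    def test_score_invariant_to_appended_decoys(self, mini_models, rng):
        model = mini_models["phaB"][0]
        core = model.consensus
        base_score = score_sequence(model, core)[0]
        appended = core + random_protein(50, rng)
        prepended = random_protein(50, rng) + core
        assert score_sequence(model, appended)[0] == pytest.approx(base_score, abs=1e-6)
        assert score_sequence(model, prepended)[0] == pytest.approx(base_score, abs=1e-6)

    def test_empty_protein_rejected(self, mini_models):
        with pytest.raises(InvalidParameterError):
            score_sequence(mini_models["phaB"][0], "")

    def test_matches_exhaustive_enumeration_on_small_models(self):
        rng = np.random.default_rng(100)
        n_cases = 120
        for _ in range(n_cases):
            m = int(rng.integers(2, 7))
            L = int(rng.integers(3, 13))
            model = random_profile(rng, m)
            protein = random_protein(L, rng)
            dp_score = score_sequence(model, protein)[0]
            oracle = enumerate_viterbi(model, encode(protein))
            assert dp_score == pytest.approx(oracle, abs=1e-9)


class TestCalibration:
    def test_shift_moves_mu_not_lambda(self, rng):
        scores = rng.gumbel(5.0, 2.0, 500)
        lam, mu = fit_gumbel(scores)
        lam2, mu2 = fit_gumbel(scores + 7.5)
        assert lam2 == pytest.approx(lam, rel=1e-6)
        assert mu2 == pytest.approx(mu + 7.5, rel=1e-6)

    def test_scaling_scores_scales_lambda_inversely(self, rng):
        scores = rng.gumbel(5.0, 2.0, 500)
        lam, mu = fit_gumbel(scores)
        lam2, mu2 = fit_gumbel(scores * 3.0)
        assert lam2 == pytest.approx(lam / 3.0, rel=1e-6)
        assert mu2 == pytest.approx(mu * 3.0, rel=1e-6)

    def test_fit_recovers_known_parameters(self, rng):
        scores = rng.gumbel(10.0, 4.0, 20_000)
        lam, mu = fit_gumbel(scores)
        assert lam == pytest.approx(1 / 4.0, rel=0.05)
        assert mu == pytest.approx(10.0, abs=0.2)

    def test_deterministic_given_seed(self, mini_models):
        from dataclasses import replace

        model = replace(mini_models["phaB"][0])  # avoid mutating the fixture
        c1 = calibrate(model, 150, np.random.default_rng(3))
        c2 = calibrate(model, 150, np.random.default_rng(3))
        assert c1 == c2

    def test_degenerate_distribution_raises(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(200, 3.0))

    def test_minimum_sample_size_enforced(self, mini_models):
        with pytest.raises(InvalidParameterError):
            calibrate(mini_models["phaB"][0], 50, np.random.default_rng(0))


class TestEvalue:
    def test_score_at_mu_hits_the_cap(self, mini_models):
        model = mini_models["phaB"][0]
        lam, mu = model.calibration
        assert evalue_of(mu, model, 500) == 500.0

    def test_linear_in_database_size(self, mini_models):
        model = mini_models["phaB"][0]
        lam, mu = model.calibration
        s = mu + 20.0
        assert evalue_of(s, model, 1000) == pytest.approx(2 * evalue_of(s, model, 500))

    def test_algebraic_inversion_gives_evalue_one(self, mini_models):
        model = mini_models["phaB"][0]
        lam, mu = model.calibration
        n = 700
        s = mu + math.log(n) / lam
        assert evalue_of(s, model, n) == pytest.approx(1.0, rel=1e-9)

    def test_monotone_decreasing_in_score(self, mini_models):
        model = mini_models["phaB"][0]
        scores = np.linspace(-10, 200, 100)
        evalues = [evalue_of(s, model, 300) for s in scores]
        assert all(e1 >= e2 for e1, e2 in zip(evalues, evalues[1:]))

    def test_uncalibrated_model_raises(self, rng):
        model = random_profile(rng, 4)
        with pytest.raises(UncalibratedModelError):
            evalue_of(10.0, model, 100)


class TestFilterHits:
    config = ScreeningConfig()

    @pytest.mark.parametrize(
        "evalue,coverage,kept",
        [
            (5e-11, 0.75, True),   # both thresholds satisfied
            (1e-10, 0.75, False),  # E-value is strictly 'less than'
            (1e-12, 0.60, False),  # coverage is strictly 'greater than'
            (1e-12, 0.601, True),
            (9.9e-11, 0.61, True),
        ],
    )
    def test_strict_threshold_boundaries(self, evalue, coverage, kept):
        hits = [make_hit(evalue=evalue, coverage=coverage)]
        assert (len(filter_hits(hits, self.config)) == 1) is kept

    def test_empty_list_passes_through(self):
        assert filter_hits([], self.config) == []

    def test_order_preserved(self):
        hits = [make_hit(protein_id=f"p{i}") for i in range(5)]
        assert [h.protein_id for h in filter_hits(hits, self.config)] == [
            f"p{i}" for i in range(5)
        ]

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            ScreeningConfig(evalue_max=0.0)
        with pytest.raises(InvalidParameterError):
            ScreeningConfig(min_query_coverage=1.5)


class TestCountCopies:
    def proteome(self, n=6, pid="P1"):
        return (pid, [(f"p{i + 1}", "ACDEFGHIKL") for i in range(n)])

    def test_three_distinct_proteins_count_three(self, mini_registry):
        hits = [
            make_hit(protein_id=p, enzyme_id="pep2", model_id="pep2:denovo")
            for p in ("p1", "p2", "p3")
        ]
        profile = count_copies(hits, mini_registry, self.proteome())
        assert profile.copy_counts["pep2"] == 3
        assert profile.proteome_size == 6

    def test_two_hits_on_same_protein_count_once(self, mini_registry):
        hits = [
            make_hit(protein_id="p1", enzyme_id="pep2", model_id="pep2:denovo"),
            make_hit(protein_id="p1", enzyme_id="pep2", model_id="pep2:denovo"),
        ]
        profile = count_copies(hits, mini_registry, self.proteome())
        assert profile.copy_counts["pep2"] == 1

    @pytest.mark.parametrize(
        "domains_hit,expected",
        [((), 0), (("PF08323",), 0), (("PF00534",), 0), (("PF08323", "PF00534"), 1)],
    )
    def test_multi_domain_enzyme_requires_all_domains(self, mini_registry, domains_hit, expected):
        hits = [
            make_hit(protein_id="p1", enzyme_id="glgA", model_id=f"glgA:{d}")
            for d in domains_hit
        ]
        profile = count_copies(hits, mini_registry, self.proteome())
        assert profile.copy_counts["glgA"] == expected

    def test_every_registry_enzyme_has_an_entry(self, mini_registry):
        profile = count_copies([], mini_registry, self.proteome())
        assert set(profile.copy_counts) == set(mini_registry.enzyme_ids)
        assert all(v == 0 for v in profile.copy_counts.values())

    def test_unknown_protein_id_raises_integrity_error(self, mini_registry):
        hits = [make_hit(protein_id="ghost", enzyme_id="pep2", model_id="pep2:denovo")]
        with pytest.raises(IntegrityError):
            count_copies(hits, mini_registry, self.proteome())

    def test_phac_any_union_with_full_registry(self, registry):
        proteome = ("P1", [(f"p{i + 1}", "ACDEFGHIKL") for i in range(4)])
        hits = [
            make_hit(protein_id="p1", enzyme_id="phaC_group1", model_id="phaC_group1:PF00561"),
            make_hit(protein_id="p2", enzyme_id="phaC_group2", model_id="phaC_group2:PF07167"),
        ]
        profile = count_copies(hits, registry, proteome)
        assert profile.copy_counts["phaC_group1"] == 1
        assert profile.copy_counts["phaC_group2"] == 1
        assert profile.copy_counts["phaC_any"] == 2
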