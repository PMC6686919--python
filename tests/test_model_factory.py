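"""Model construction: identity, dereplication, alignment, trimming, profiles."""

import numpy as np
import pytest

from reservescan.alphabet import AMINO_ACIDS, UNIFORM_BACKGROUND
from reservescan.errors import (
    ConfigurationError,
    DegenerateAlignmentError,
    InvalidParameterError,
)
from reservescan.model_factory import (
    Msa,
    build_msa,
    build_profile,
    dereplicate,
    pairwise_identity,
    read_hmmer3_profile,
    resolve_models,
    trim_termini,
)
from reservescan.registry import ModelPolicy
from reservescan.synthetic_cohort import mutate_homolog, synthesize_homologs


def random_seq(length, seed):
    return "".join(np.random.default_rng(seed).choice(list(AMINO_ACIDS), length))


class TestPairwiseIdentity:
    def test_identical_sequences_have_identity_one(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_single_mismatch_over_nine_columns(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIR") == pytest.approx(8 / 9)

    def test_symmetric_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(5, 60)))
            b = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(5, 60)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a), abs=1e-12)

    def test_identity_one_only_for_identical(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = "".join(rng.choice(list(AMINO_ACIDS), 30))
            b = mutate_homolog(a, 0.9, rng)
            assert pairwise_identity(a, b) < 1.0

    def test_gap_handling_shorter_sequence(self):
        # best alignment of ACDEF vs ACEF keeps 4 matches over 5 columns
        assert pairwise_identity("ACDEF", "ACEF") == pytest.approx(4 / 5)

    def test_rejects_empty_input(self):
        with pytest.raises(InvalidParameterError):
            pairwise_identity("", "ACD")


class TestDereplicate:
    def test_exact_duplicates_collapse(self):
        assert dereplicate(["ACDEFGHIKL", "ACDEFGHIKL"]) == ["ACDEFGHIKL"]

    def test_pair_at_97_percent_survives_098_threshold(self):
        a = random_seq(100, 2)
        b = mutate_homolog(a, 0.97, np.random.default_rng(3))
        assert pairwise_identity(a, b) == pytest.approx(0.97)
        assert dereplicate([a, b], threshold=0.98) == [a, b]

    def test_pair_above_threshold_collapses(self):
        a = random_seq(100, 4)
        b = mutate_homolog(a, 0.99, np.random.default_rng(5))
        assert dereplicate([a, b], threshold=0.98) == [a]

    def test_idempotent_on_random_sets(self):
        rng = np.random.default_rng(6)
        base = random_seq(60, 7)
        seqs = [mutate_homolog(base, rng.uniform(0.7, 1.0), rng) for _ in range(12)]
        once = dereplicate(seqs)
        assert dereplicate(once) == once

    def test_output_never_larger_and_order_preserved(self):
        rng = np.random.default_rng(8)
        base = random_seq(50, 9)
        seqs = [mutate_homolog(base, rng.uniform(0.9, 1.0), rng) for _ in range(10)]
        kept = dereplicate(seqs)
        assert len(kept) <= len(seqs)
        positions = [seqs.index(k) for k in kept]
        assert positions == sorted(positions)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            dereplicate(["ACD"], threshold=1.5)


class TestBuildMsa:
    def test_two_identical_sequences_align_gap_free(self):
        msa = build_msa(["ACDEF", "ACDEF"])
        assert msa.column_count == 5
        assert all("-" not in row for _, row in msa.rows)

    def test_single_deletion_gives_five_columns_with_one_gap(self):
        msa = build_msa(["ACDEF", "ACEF"])
        assert msa.column_count == 5
        gaps = sum(row.count("-") for _, row in msa.rows)
        assert gaps == 1

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(10)
        base = random_seq(40, 11)
        inputs = [mutate_homolog(base, rng.uniform(0.6, 0.95), rng) for _ in range(6)]
        msa = build_msa(inputs)
        recovered = {row.replace("-", "") for _, row in msa.rows}
        assert recovered == set(inputs)

    def test_requires_two_sequences(self):
        with pytest.raises(InvalidParameterError):
            build_msa(["ACDEF"])


class TestTrimTermini:
    def test_gap_free_alignment_unchanged(self):
        msa = build_msa(["ACDEF", "ACDEF", "ACDEF"])
        assert trim_termini(msa) is msa

    def test_sparse_leading_columns_removed(self):
        rows = (
            ("s1", "AC" + "DEFGHIKL"),
            ("s2", "--" + "DEFGHIKL"),
            ("s3", "--" + "DEFGHIKL"),
            ("s4", "--" + "DEFGHIKL"),
        )
        trimmed = trim_termini(Msa(rows=rows), min_occupancy=0.5)
        assert trimmed.column_count == 8
        assert all(r == "DEFGHIKL" for _, r in trimmed.rows)

    def test_zero_threshold_is_vacuous(self):
        rows = (("s1", "A---"), ("s2", "-C--"))
        msa = Msa(rows=rows)
        assert trim_termini(msa, min_occupancy=0.0).column_count == 4

    def test_error_when_everything_would_be_trimmed(self):
        rows = (("s1", "A---"), ("s2", "---C"), ("s3", "----"), ("s4", "----"))
        with pytest.raises(DegenerateAlignmentError):
            trim_termini(Msa(rows=rows), min_occupancy=0.9)

    def test_interior_columns_untouched(self):
        rows = (("s1", "A-C-E"), ("s2", "A-C-E"))
        msa = Msa(rows=rows)
        assert trim_termini(msa, min_occupancy=0.5).column_count == 5


class TestBuildProfile:
    def test_hand_computed_emission_with_pseudocounts(self):
        msa = Msa(rows=tuple((f"s{i}", "ACD") for i in range(5)))
        w = 2.0
        model = build_profile(msa, pseudocount_weight=w)
        assert model.match_length == 3
        q_a = UNIFORM_BACKGROUND[0]
        expected = (5 + w * q_a) / (5 + w)
        assert model.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(expected)
        assert model.query_length_aa == 3

    def test_all_probability_rows_normalized(self):
        rng = np.random.default_rng(12)
        base = random_seq(50, 13)
        seqs = [mutate_homolog(base, rng.uniform(0.7, 0.95), rng) for _ in range(8)]
        model = build_profile(build_msa(seqs), pseudocount_weight=1.0)
        assert np.allclose(model.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.t_match.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.t_insert.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.t_delete.sum(axis=1), 1.0, atol=1e-9)

    def test_small_pseudocount_limit_recovers_empirical_frequencies(self):
        rows = tuple((f"s{i}", seq) for i, seq in enumerate(["AC", "AC", "AD", "AD"]))
        model = build_profile(Msa(rows=rows), pseudocount_weight=1e-9)
        a_col = model.match_emissions[0]
        assert a_col[AMINO_ACIDS.index("A")] == pytest.approx(1.0, abs=1e-8)
        second = model.match_emissions[1]
        assert second[AMINO_ACIDS.index("C")] == pytest.approx(0.5, abs=1e-8)
        assert second[AMINO_ACIDS.index("D")] == pytest.approx(0.5, abs=1e-8)

    def test_no_dense_column_raises(self):
        rows = (
            ("s1", "A---"), ("s2", "-C--"), ("s3", "--D-"), ("s4", "---E"),
            ("s5", "----"), ("s6", "----"), ("s7", "----"), ("s8", "----"),
        )
        with pytest.raises(DegenerateAlignmentError):
            build_profile(Msa(rows=rows), pseudocount_weight=1.0)

    def test_nonpositive_pseudocount_rejected(self):
        msa = Msa(rows=(("a", "AC"), ("b", "AC")))
        with pytest.raises(InvalidParameterError):
            build_profile(msa, pseudocount_weight=0.0)


class TestResolveModels:
    def test_de_novo_enzyme_gets_single_full_model(self, registry, rng):
        seed = registry["ppk1"]
        assert seed.model_policy is ModelPolicy.DE_NOVO_FULL
        homologs = synthesize_homologs("ppk1", seed.sequence, 8, (0.8, 0.95), rng)
        models = resolve_models(seed, {"ppk1": homologs}, {})
        assert len(models) == 1
        assert models[0].model_id == "ppk1:denovo"
        # full-length model: match states close to seed length
        assert models[0].match_length >= 0.9 * seed.length_aa

    def test_single_domain_enzyme_gets_one_domain_model(self, registry, mini_models):
        seed = registry["phaB"]
        assert seed.pfam_domain_ids == ("PF00106",)
        domain_store = {"PF00106": mini_models["phaB"][0]}
        models = resolve_models(seed, {}, domain_store)
        assert len(models) == 1
        assert models[0].model_id == "phaB:PF00106"

    def test_tres_is_de_novo_despite_two_domains(self, registry, rng):
        seed = registry["treS"]
        assert len(seed.pfam_domain_ids) == 2
        assert seed.model_policy is ModelPolicy.DE_NOVO_FULL
        homologs = synthesize_homologs("treS", seed.sequence, 6, (0.85, 0.95), rng)
        models = resolve_models(seed, {"treS": homologs}, {})
        assert [m.model_id for m in models] == ["treS:denovo"]

    def test_missing_stores_raise_configuration_error_naming_enzyme(self, registry):
        with pytest.raises(ConfigurationError, match="ppk1"):
            resolve_models(registry["ppk1"], {}, {})
        with pytest.raises(ConfigurationError, match="phaB"):
            resolve_models(registry["phaB"], {}, {})

    def test_table_policy_flags(self, registry):
        de_novo = {e.enzyme_id for e in registry if e.model_policy is ModelPolicy.DE_NOVO_FULL}
        assert de_novo == {"ppk1", "glgB_gh57", "glgB_gh13", "treS", "pep2", "glgE"}


class TestModelQuality:
    def test_model_scores_seed_above_all_shuffles(self, mini_registry, mini_models):
        from reservescan.homology_search import score_sequence

        seed = mini_registry["pep2"]
        model = mini_models["pep2"][0]
        seed_score = score_sequence(model, seed.sequence)[0]
        rng = np.random.default_rng(77)
        letters = list(seed.sequence)
        for _ in range(100):
            rng.shuffle(letters)
            shuffled_score = score_sequence(model, "".join(letters))[0]
            assert seed_score > shuffled_score

    def test_dereplicated_set_pairwise_identities_below_threshold(self):
        rng = np.random.default_rng(14)
        base = random_seq(60, 15)
        seqs = [mutate_homolog(base, rng.uniform(0.9, 1.0), rng) for _ in range(10)]
        kept = dereplicate(seqs, threshold=0.95)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pairwise_identity(kept[i], kept[j]) <= 0.95


class TestSerialization:
    def test_profile_json_roundtrip(self, mini_models):
        from reservescan.model_factory import ProfileModel

        model = mini_models["glgA"][0]
        clone = ProfileModel.from_dict(model.to_dict())
        assert clone.model_id == model.model_id
        assert np.allclose(clone.match_emissions, model.match_emissions)
        assert clone.calibration == pytest.approx(model.calibration)

    def test_msa_stockholm_roundtrip(self, tmp_path):
        msa = build_msa(["ACDEF", "ACEF", "ACDEH"])
        path = tmp_path / "aln.sto"
        msa.to_stockholm(path)
        back = Msa.from_stockholm(path)
        assert back.rows == msa.rows

    def test_hmmer3_importer_matches_pyhmmer_built_model(self, tmp_path):
        pyhmmer = pytest.importorskip("pyhmmer")

        rng = np.random.default_rng(16)
        base = random_seq(40, 17)
        seqs = [mutate_homolog(base, rng.uniform(0.8, 0.95), rng) for _ in range(6)]
        msa = build_msa(seqs)
        alphabet = pyhmmer.easel.Alphabet.amino()
        digital = pyhmmer.easel.TextMSA(
            name=b"toy",
            sequences=[
                pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=row)
                for i, (_, row) in enumerate(msa.rows)
            ],
        ).digitize(alphabet)
        builder = pyhmmer.plan7.Builder(alphabet)
        hmm, _, _ = builder.build_msa(digital, pyhmmer.plan7.Background(alphabet))
        path = tmp_path / "toy.hmm"
        with path.open("wb") as fh:
            hmm.write(fh)
        imported = read_hmmer3_profile(path)
        assert imported.match_length == hmm.M
        # consensus residues of the imported emissions match pyhmmer's
        consensus = imported.consensus
        assert consensus == (hmm.consensus or "").upper()
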