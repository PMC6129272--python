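import h5py
import numpy as np
import pytest

import dfim
from dfim.attribution import ReferenceSpec
from dfim.fis import _policy_best
from dfim.mutation import MutationSpec
from dfim.seqdata import BASE_INDEX, SequenceError, motif_locus, nucleotide_locus

from conftest import random_conv_model


def encode(seq):
    return dfim.one_hot_encode(seq)


class TestProductModelHandValues:
    """Interaction scores on Y = X[A,0] * X[A,1], computed by hand."""

    def test_nucleotide_fis_is_one(self, product_model):
        # C_X[A,1] = X[A,0]*X[A,1] = 1; after A0->C: C_X'[A,1] = 0
        backend = dfim.GradInputBackend()
        score = dfim.fis_nucleotide(product_model, backend, encode("AA"), 0, "C", 1)
        assert score == 1.0

    def test_pairwise_ism_is_minus_one(self, product_model):
        x = encode("AA")
        s = MutationSpec("point", nucleotide_locus("A", 0), "C")
        t = MutationSpec("point", nucleotide_locus("A", 1), "C")
        # ISM(joint) = 1, ISM(source) = ISM(target) = 1 -> 1 - 2 = -1
        assert dfim.pairwise_ism_interaction(product_model, x, s, t) == -1.0

    def test_fis_sign_tracks_mixed_second_difference(self, product_model):
        # On Y = X[A,0]*X[A,1] (an AND gate), FIS carries the sign of the
        # mixed second difference Y(AA)-Y(CA)-Y(AC)+Y(CC) = +1, while the
        # joint-minus-sum ISM interaction is its negative: 1 - (1+1) = -1.
        backend = dfim.GradInputBackend()
        fis = dfim.fis_nucleotide(product_model, backend, encode("AA"), 0, "C", 1)
        s = MutationSpec("point", nucleotide_locus("A", 0), "C")
        t = MutationSpec("point", nucleotide_locus("A", 1), "C")
        ism = dfim.pairwise_ism_interaction(product_model, encode("AA"), s, t)
        mixed_second_diff = 1.0 - 0.0 - 0.0 + 0.0
        assert np.sign(fis) == np.sign(mixed_second_diff) == 1.0
        assert ism == -mixed_second_diff

    def test_motif_target_extends_product(self, product_model):
        # 3-mer target over positions 1..3 of "AAAA": only (A,1) carries score
        backend = dfim.GradInputBackend()
        x = encode("AAAA")
        target = motif_locus(x, 1, 4)
        score = dfim.fis_motif_target(product_model, backend, x, 0, "C", target)
        # brute-force oracle: two explicit backend calls
        mutated = encode("CAAA")
        expected = dfim.importance_of_locus(
            dfim.grad_input_importance(product_model, x), target
        ) - dfim.importance_of_locus(
            dfim.grad_input_importance(product_model, mutated), target
        )
        assert score == expected == 1.0


class TestDefinitionalOracle:
    """Engine scores must equal two independent backend calls on
    explicitly constructed sequences, bit-exactly."""

    @pytest.mark.parametrize("backend_kind", ["grad_input", "ref_diff"])
    def test_random_cases_match_bruteforce(self, rng, backend_kind):
        L = 30
        for case in range(50):
            model = random_conv_model(np.random.default_rng(case), L)
            seq = "".join(rng.choice(list("ACGT"), L))
            x = encode(seq)
            s, t = rng.choice(L, size=2, replace=False)
            alpha = seq[s]
            gamma = rng.choice([b for b in "ACGT" if b != alpha])
            if backend_kind == "grad_input":
                backend = dfim.GradInputBackend()
                imp = dfim.grad_input_importance
            else:
                spec = ReferenceSpec("dinuc_shuffle", n_references=2, shuffle_seed=9, m_steps=4)
                backend = dfim.RefDiffBackend(spec)
                imp = lambda m, z: dfim.ref_diff_importance(m, z, spec)
            engine = dfim.fis_nucleotide(model, backend, x, int(s), gamma, int(t))
            # oracle: build the mutant by string editing, call the backend twice
            mut_seq = seq[: int(s)] + gamma + seq[int(s) + 1:]
            beta = seq[int(t)]
            oracle = (
                imp(model, x).scores[BASE_INDEX[beta], int(t)]
                - imp(model, encode(mut_seq)).scores[BASE_INDEX[beta], int(t)]
            )
            assert engine == oracle

    def test_motif_motif_matches_bruteforce(self, rng):
        L = 30
        model = random_conv_model(rng, L)
        seq = "".join(rng.choice(list("ACGT"), L))
        x = encode(seq)
        src, tgt = motif_locus(x, 2, 8), motif_locus(x, 15, 21)
        backend = dfim.GradInputBackend()
        engine = dfim.fis_motif_motif(model, backend, x, src, 0.46, tgt)
        mutated = dfim.apply_background_mutation(x, src, 0.46)
        oracle = dfim.importance_of_locus(
            dfim.grad_input_importance(model, x), tgt
        ) - dfim.importance_of_locus(dfim.grad_input_importance(model, mutated), tgt)
        assert engine == oracle


class TestZeroInteractionLaw:
    """Every interaction score vanishes identically on a linear model."""

    def test_all_fis_forms_zero(self, linear_model, random_sequence, rng):
        x = encode(random_sequence)
        backend = dfim.GradInputBackend()
        for _ in range(30):
            s, t = rng.choice(30, size=2, replace=False)
            gamma = rng.choice([b for b in "ACGT" if b != random_sequence[s]])
            assert dfim.fis_nucleotide(linear_model, backend, x, int(s), gamma, int(t)) == 0.0
        assert np.nanmax(np.abs(dfim.fis_profile(linear_model, backend, x, 4, "C"
                          if random_sequence[4] != "C" else "G"))) == 0.0
        src, tgt = motif_locus(x, 1, 6), motif_locus(x, 12, 18)
        assert dfim.fis_motif_motif(linear_model, backend, x, src, 0.46, tgt) == 0.0

    def test_dfim_map_all_zero_off_diagonal(self, linear_model, random_sequence):
        backend = dfim.GradInputBackend()
        m = dfim.dfim_map(linear_model, backend, encode(random_sequence))
        assert np.all(m.scores[~m.mask] == 0.0)

    def test_pairwise_ism_zero_by_additivity(self, linear_model, random_sequence, rng):
        x = encode(random_sequence)
        for _ in range(10):
            s, t = rng.choice(30, size=2, replace=False)
            specs = []
            for pos in (int(s), int(t)):
                alpha = random_sequence[pos]
                gamma = rng.choice([b for b in "ACGT" if b != alpha])
                specs.append(MutationSpec("point", nucleotide_locus(alpha, pos), str(gamma)))
            assert abs(dfim.pairwise_ism_interaction(linear_model, x, *specs)) < 1e-12


class TestProfileAndMaxFis:
    def test_profile_matches_per_target_calls(self, rng):
        model = random_conv_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 30))
        x = encode(seq)
        backend = dfim.GradInputBackend()
        profile = dfim.fis_profile(model, backend, x, 9, "T" if seq[9] != "T" else "A")
        gamma = "T" if seq[9] != "T" else "A"
        for t in (0, 5, 20, 29):
            beta = seq[t]
            per_call = dfim.fis_nucleotide(model, backend, x, 9, gamma, t)
            assert profile[BASE_INDEX[beta], t] == per_call
        assert np.all(np.isnan(profile[:, 9]))

    def test_profile_costs_two_evaluations(self, rng):
        model = random_conv_model(rng)
        x = encode("".join(rng.choice(list("ACGT"), 30)))
        backend = dfim.GradInputBackend()
        dfim.fis_profile(model, backend, x, 3, "C" if x.observed_base(3) != "C" else "G")
        assert backend.n_evaluations == 2
        base = backend.importance(model, x)
        backend.reset_counter()
        dfim.fis_profile(model, backend, x, 3, "C" if x.observed_base(3) != "C" else "G", base)
        assert backend.n_evaluations == 1

    def test_policy_semantics_and_tiebreak(self):
        cases = [("C", 0.2), ("G", -0.5), ("T", 0.1)]
        assert _policy_best(cases, "signed") == (0.2, "C")
        assert _policy_best(cases, "abs") == (-0.5, "G")
        ties = [("C", 0.0), ("G", 0.0), ("T", 0.0)]
        assert _policy_best(ties, "signed") == (0.0, "C")

    def test_max_fis_on_linear_breaks_ties_alphabetically(self, linear_model):
        x = encode("A" * 30)
        backend = dfim.GradInputBackend()
        for policy in ("signed", "abs"):
            score, gamma = dfim.max_fis(linear_model, backend, x, 2, 10, policy)
            assert score == 0.0 and gamma == "C"

    def test_signed_max_dominates_each_mutant(self, rng):
        model = random_conv_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 30))
        x = encode(seq)
        backend = dfim.GradInputBackend()
        base = backend.importance(model, x)
        for _ in range(10):
            s, t = rng.choice(30, size=2, replace=False)
            best, _ = dfim.max_fis(model, backend, x, int(s), int(t), "signed", base)
            for gamma in [b for b in "ACGT" if b != seq[s]]:
                assert best >= dfim.fis_nucleotide(model, backend, x, int(s), gamma, int(t), base)

    def test_self_interaction_rejected(self, linear_model):
        x = encode("ACGTACGT" + "A" * 22)
        backend = dfim.GradInputBackend()
        with pytest.raises(SequenceError, match="self-interaction"):
            dfim.fis_nucleotide(linear_model, backend, x, 5, "A", 5)


class TestDfimMap:
    def test_rows_equal_policy_max_over_profiles(self, rng):
        model = random_conv_model(rng, 12)
        seq = "".join(rng.choice(list("ACGT"), 12))
        x = encode(seq)
        backend = dfim.GradInputBackend()
        m = dfim.dfim_map(model, backend, x, policy="abs")
        base = backend.importance(model, x)
        obs = np.argmax(x.matrix, axis=0)
        for s in (0, 4, 11):
            stacked = [
                dfim.fis_profile(model, backend, x, s, g, base)[obs, np.arange(12)]
                for g in "ACGT"
                if g != seq[s]
            ]
            stacked = np.stack(stacked)
            keyed = np.where(np.isnan(stacked), -np.inf, np.abs(stacked))
            pick = np.argmax(keyed, axis=0)
            expected = stacked[pick, np.arange(12)]
            row = m.scores[s]
            assert np.array_equal(row[~m.mask[s]], expected[~m.mask[s]])

    def test_diagonal_masked(self, linear_model, random_sequence):
        m = dfim.dfim_map(linear_model, dfim.GradInputBackend(), encode(random_sequence))
        assert np.all(np.isnan(np.diag(m.scores)))
        assert np.array_equal(m.mask, np.eye(30, dtype=bool))

    def test_directionality_not_symmetrized(self, rng):
        model = random_conv_model(rng, 12)
        x = encode("".join(rng.choice(list("ACGT"), 12)))
        m = dfim.dfim_map(model, dfim.GradInputBackend(), x)
        off = m.scores[~m.mask]
        asym = np.abs(m.scores - m.scores.T)
        assert np.nanmax(asym) > 0  # FIS(t|s) and FIS(s|t) computed independently


class TestMotifOps:
    def test_motif_target_equals_per_position_sum(self, rng):
        model = random_conv_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 30))
        x = encode(seq)
        backend = dfim.GradInputBackend()
        target = motif_locus(x, 10, 16)
        gamma = "G" if seq[2] != "G" else "T"
        whole = dfim.fis_motif_target(model, backend, x, 2, gamma, target)
        parts = sum(
            dfim.fis_nucleotide(model, backend, x, 2, gamma, t) for t in range(10, 16)
        )
        assert np.isclose(whole, parts, rtol=0, atol=1e-12)

    def test_source_inside_target_rejected(self, linear_model):
        x = encode("ACGTACGTACGT" + "A" * 18)
        with pytest.raises(SequenceError, match="inside the target"):
            dfim.fis_motif_target(
                linear_model, dfim.GradInputBackend(), x, 12, "C", motif_locus(x, 10, 16)
            )

    def test_overlapping_motifs_rejected(self, linear_model):
        x = encode("ACGTACGTACGT" + "A" * 18)
        with pytest.raises(SequenceError, match="overlap"):
            dfim.fis_motif_motif(
                linear_model, dfim.GradInputBackend(), x,
                motif_locus(x, 2, 8), 0.46, motif_locus(x, 6, 12),
            )

    def test_motif_motif_two_evaluations(self, rng):
        model = random_conv_model(rng)
        x = encode("".join(rng.choice(list("ACGT"), 30)))
        backend = dfim.GradInputBackend()
        dfim.fis_motif_motif(model, backend, x, motif_locus(x, 0, 6), 0.46, motif_locus(x, 20, 26))
        assert backend.n_evaluations == 2


class TestComplexity:
    def test_all_pairs_map_uses_3l_plus_1_evaluations(self, rng):
        L = 24
        model = random_conv_model(rng, L)
        x = encode("".join(rng.choice(list("ACGT"), L)))
        backend = dfim.GradInputBackend()
        dfim.dfim_map(model, backend, x)
        assert backend.n_evaluations == 3 * L + 1

    def test_f_sources_use_f_plus_1_evaluations(self, rng):
        model = random_conv_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 30))
        x = encode(seq)
        backend = dfim.GradInputBackend()
        specs = [
            MutationSpec("point", nucleotide_locus(seq[i], i),
                         "A" if seq[i] != "A" else "C")
            for i in (2, 9, 15, 21, 28)
        ]
        profiles = dfim.interaction_profiles(model, backend, x, specs)
        assert backend.n_evaluations == len(specs) + 1
        assert len(profiles) == 5
        assert all(np.all(np.isnan(p[:, s.source.start])) for p, s in zip(profiles, specs))


class TestIsmSymmetry:
    def test_swapping_arguments_gives_identical_score(self, rng):
        model = random_conv_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 30))
        x = encode(seq)
        for _ in range(10):
            s, t = rng.choice(30, size=2, replace=False)
            a = MutationSpec("point", nucleotide_locus(seq[s], int(s)),
                             "A" if seq[s] != "A" else "C")
            b = MutationSpec("point", nucleotide_locus(seq[t], int(t)),
                             "G" if seq[t] != "G" else "T")
            assert dfim.pairwise_ism_interaction(model, x, a, b) == \
                   dfim.pairwise_ism_interaction(model, x, b, a)

    def test_overlapping_features_rejected(self, linear_model):
        x = encode("ACGT" * 8)
        a = MutationSpec("motif_background", motif_locus(x, 0, 6), f_gc=0.4)
        b = MutationSpec("motif_background", motif_locus(x, 4, 10), f_gc=0.4)
        with pytest.raises(SequenceError, match="overlap"):
            dfim.pairwise_ism_interaction(linear_model, x, a, b)


class TestSerialization:
    def test_records_dataframe_and_tsv(self, tmp_path):
        records = [
            dfim.FISRecord("s1", nucleotide_locus("A", 3), "C",
                           nucleotide_locus("G", 7), -0.25, "grad_input")
        ]
        df = dfim.records_to_dataframe(records)
        assert df.loc[0, "abs_score"] == 0.25
        assert list(df.columns)[:4] == ["sequence_id", "source_start", "source_end", "source_bases"]
        dfim.records_to_tsv(records, tmp_path / "r.tsv")
        assert "grad_input" in (tmp_path / "r.tsv").read_text()

    def test_maps_hdf5_round_trip(self, tmp_path, linear_model, random_sequence):
        m = dfim.dfim_map(linear_model, dfim.GradInputBackend(), encode(random_sequence))
        dfim.dfim_maps_to_hdf5([m], tmp_path / "maps.h5")
        with h5py.File(tmp_path / "maps.h5") as fh:
            grp = fh[m.sequence_id]
            assert grp.attrs["policy"] == "abs"
            stored = grp["scores"][...]
            assert np.array_equal(stored[~m.mask], m.scores[~m.mask])
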