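import numpy as np
import pytest

from mirbridge.dataio import Alphabet, SequenceStore
from mirbridge.featsim import (
    DINUCLEOTIDES,
    ZERO_DISTANCE_EPS,
    PropertyTable,
    PseVector,
    default_amino_acid_table,
    default_dinucleotide_table,
    feature_similarity,
    feature_similarity_from_store,
    pseaac,
    psednc,
)


class TestPropertyTables:
    @pytest.mark.parametrize(
        "loader,n_props,n_items",
        [(default_dinucleotide_table, 6, 16), (default_amino_acid_table, 8, 20)],
    )
    def test_standardized(self, loader, n_props, n_items):
        table = loader()
        assert table.values.shape == (n_props, n_items)
        assert np.allclose(table.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(table.values.std(axis=1), 1.0, atol=1e-9)

    def test_complementary_dinucleotides_share_values(self):
        table = default_dinucleotide_table()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        col = {d: i for i, d in enumerate(table.items)}
        for d in DINUCLEOTIDES:
            rc = comp[d[1]] + comp[d[0]]
            assert np.allclose(table.values[:, col[d]], table.values[:, col[rc]])

    def test_constant_row_rejected(self):
        t = PropertyTable("t", ["AA", "AC"], ["p"], np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError, match="constant"):
            t.standardized()


def straight_line_psednc(seq, lam, omega, table):
    """Independent step-by-step evaluation of the pseudo dinucleotide
    composition, written as plain loops."""
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    col = {d: i for i, d in enumerate(table.items)}
    freqs = [dinucs.count(d) / len(dinucs) for d in table.items]

    def theta_pair(d1, d2):
        diffs = [
            (table.values[p, col[d1]] - table.values[p, col[d2]]) ** 2
            for p in range(table.values.shape[0])
        ]
        return sum(diffs) / len(diffs)

    thetas = []
    for j in range(1, lam + 1):
        terms = [theta_pair(dinucs[i], dinucs[i + j]) for i in range(len(dinucs) - j)]
        thetas.append(sum(terms) / len(terms))
    denom = 1 + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


def straight_line_pseaac(seq, tau, omega, table):
    col = {a: i for i, a in enumerate(table.items)}
    freqs = [seq.count(a) / len(seq) for a in table.items]

    def theta_pair(a1, a2):
        diffs = [
            (table.values[p, col[a2]] - table.values[p, col[a1]]) ** 2
            for p in range(table.values.shape[0])
        ]
        return sum(diffs) / len(diffs)

    thetas = []
    for j in range(1, tau + 1):
        terms = [theta_pair(seq[i], seq[i + j]) for i in range(len(seq) - j)]
        thetas.append(sum(terms) / len(terms))
    denom = 1 + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


class TestPseDNC:
    def test_zero_weight_is_plain_composition(self):
        v = psednc("ACGTACGTACGT", lam=3, omega1=0.0)
        assert v.values.shape == (19,)
        assert np.allclose(v.values[16:], 0.0)
        assert v.values[:16].sum() == pytest.approx(1.0)

    def test_homopolymer_is_indicator(self):
        v = psednc("A" * 30, lam=5, omega1=0.4)
        aa = DINUCLEOTIDES.index("AA")
        assert v.values[aa] == pytest.approx(1.0)
        assert np.allclose(np.delete(v.values, aa), 0.0)

    def test_matches_straight_line_oracle(self):
        table = default_dinucleotide_table()
        seq = "ACGTACGTACGTACGT"
        v = psednc(seq, lam=2, omega1=0.1, props=table)
        expected = straight_line_psednc(seq, 2, 0.1, table)
        assert np.allclose(v.values, expected, atol=1e-12)

    def test_too_short_sequence_names_bound(self):
        with pytest.raises(ValueError, match="lambda=10"):
            psednc("ACGTACG", lam=10)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            psednc("ACGTACGT", lam=0)

    def test_ambiguous_positions_dropped(self):
        v1 = psednc("ACGT*ACGTACGT".replace("*", ""), lam=2, omega1=0.1)
        v2 = psednc("ACGT*ACGTACGT", lam=2, omega1=0.1)
        assert np.allclose(v1.values, v2.values)

    @pytest.mark.parametrize("lam", [10, 15, 20])
    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0])
    def test_unit_sum_across_calibration_grid(self, lam, omega):
        rng = np.random.default_rng(lam * 100 + int(omega * 10))
        seq = "".join(rng.choice(list("ACGT"), size=120))
        v = psednc(seq, lam=lam, omega1=omega)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (v.values >= 0).all()
        assert v.values.shape == (16 + lam,)


class TestPseAAC:
    def test_zero_weight_is_composition(self):
        v = pseaac("MKVLAWGRENQ" * 3, tau=4, omega2=0.0)
        assert np.allclose(v.values[20:], 0.0)
        assert v.values[:20].sum() == pytest.approx(1.0)

    def test_homopolymer_is_indicator(self):
        table = default_amino_acid_table()
        v = pseaac("G" * 25, tau=6, omega2=0.5)
        g = table.items.index("G")
        assert v.values[g] == pytest.approx(1.0)

    def test_matches_straight_line_oracle(self):
        table = default_amino_acid_table()
        seq = "MKVLAWGRENQDFHISTPCYM"[:25] + "AGKV"
        seq = seq[:25]
        v = pseaac(seq, tau=11, omega2=0.5, props=table)
        expected = straight_line_pseaac(seq, 11, 0.5, table)
        assert np.allclose(v.values, expected, atol=1e-12)

    @pytest.mark.parametrize("tau", [10, 15, 20])
    @pytest.mark.parametrize("omega", [0.05, 0.25, 0.5])
    def test_unit_sum_across_calibration_grid(self, tau, omega):
        rng = np.random.default_rng(tau * 7 + int(omega * 100))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        v = pseaac(seq, tau=tau, omega2=omega)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert v.values.shape == (20 + tau,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="tau=11"):
            pseaac("MKVLA", tau=11)


class TestFeatureSimilarity:
    def test_reciprocal_of_distance(self):
        a = PseVector(np.array([1.0, 0.0]))
        b = PseVector(np.array([0.0, 1.0]))  # not unit-sum irrelevant here
        c = PseVector(np.array([1.0, 2.0]))
        sim = feature_similarity([a, b, c], ["a", "b", "c"])
        d = np.linalg.norm(a.values - b.values)
        assert sim.values[0, 1] == pytest.approx(1.0 / d)
        assert sim.values[0, 2] == pytest.approx(0.5)

    def test_identical_vectors_capped(self):
        a = PseVector(np.array([0.5, 0.5]))
        sim = feature_similarity([a, PseVector(a.values.copy())], ["a", "b"])
        assert sim.values[0, 1] == pytest.approx(1.0 / ZERO_DISTANCE_EPS)

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            feature_similarity(
                [PseVector(np.zeros(3)), PseVector(np.zeros(4))], ["a", "b"]
            )

    def test_matches_brute_force_distance_oracle(self):
        rng = np.random.default_rng(3)
        vecs = [rng.dirichlet(np.ones(18)) for _ in range(5)]
        sim = feature_similarity([PseVector(v) for v in vecs], list("abcde"))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                d = float(np.sqrt(sum((vecs[i][k] - vecs[j][k]) ** 2 for k in range(18))))
                assert sim.values[i, j] == pytest.approx(1.0 / d, rel=1e-12)

    def test_short_sequences_excluded_with_zero_rows(self, caplog):
        store = SequenceStore(
            {"a": "ACGTACGTACGTACGTACGT", "b": "ACG"}, Alphabet.NUCLEOTIDE
        )
        with caplog.at_level("WARNING"):
            sim = feature_similarity_from_store(store, ["a", "b"], lam=10)
        assert np.allclose(sim.values[1, :], 0.0)
        assert np.allclose(sim.values[:, 1], 0.0)
        assert any("too short" in r.message for r in caplog.records)
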