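import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from thermoprot._tables import (
    CODON_COUNTS,
    CONJOINT_TRIAD_CLASSES,
    CTD_PROPERTIES,
    RESIDUE_GROUPS,
)
from thermoprot.descriptors import (
    DEFAULT_K,
    DESCRIPTOR_NAMES,
    block_names,
    encode,
    encode_composition_family,
    encode_ctd,
    encode_ctriad,
    encode_dde,
    encode_kspaced_pairs,
    get_spec,
)
from thermoprot.sequence_io import AMINO_ACIDS

valid_sequences = st.text(alphabet=AMINO_ACIDS, min_size=20, max_size=60)


class TestPackagedTables:
    def test_residue_groups_partition_alphabet(self):
        joined = "".join(RESIDUE_GROUPS.values())
        assert sorted(joined) == sorted(AMINO_ACIDS)

    def test_ctd_properties_partition_alphabet(self):
        assert len(CTD_PROPERTIES) == 13
        for prop, groups in CTD_PROPERTIES.items():
            assert sorted("".join(groups)) == sorted(AMINO_ACIDS), prop

    def test_conjoint_triad_partition(self):
        joined = "".join(CONJOINT_TRIAD_CLASSES)
        assert len(CONJOINT_TRIAD_CLASSES) == 7
        assert sorted(joined) == sorted(AMINO_ACIDS)

    def test_codon_counts_sum_to_61(self):
        assert sum(CODON_COUNTS.values()) == 61


DIMENSIONS = {
    "AAC": 20, "DPC": 400, "TPC": 8000, "GAAC": 5, "GDPC": 25, "GTPC": 125,
    "DDE": 400, "CTDC": 39, "CTDT": 39, "CTDD": 195, "CTriad": 343,
}


class TestDimensions:
    @pytest.mark.parametrize("name,dim", sorted(DIMENSIONS.items()))
    def test_fixed_dimensions(self, name, dim, rng):
        spec = get_spec(name)
        assert spec.dimension == dim
        assert encode(spec, random_sequence(rng, 40)).shape == (dim,)

    @pytest.mark.parametrize("name,unit", [("CKSAAP", 400), ("CKSAAGP", 25), ("KSCTriad", 343)])
    @pytest.mark.parametrize("k_max", range(6))
    def test_gapped_dimensions_closed_form(self, name, unit, k_max, rng):
        spec = get_spec(name, k_max=k_max)
        assert spec.dimension == unit * (k_max + 1)
        seq = random_sequence(rng, 2 * k_max + 10)
        assert encode(spec, seq).shape == (spec.dimension,)

    def test_total_default_dimension_frozen(self):
        total = sum(get_spec(n).dimension for n in DESCRIPTOR_NAMES)
        assert total == 13170  # all 14 blocks at default gap settings


class TestCompositionFamilies:
    def test_aac_single_residue(self):
        v = encode(get_spec("AAC"), "A" * 20)
        assert v[AMINO_ACIDS.index("A")] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_aac_pangram_uniform(self):
        v = encode(get_spec("AAC"), AMINO_ACIDS)
        np.testing.assert_allclose(v, 0.05)

    def test_dpc_on_homopolymer(self):
        v = encode_composition_family(2, grouped=False, sequence="AAA")
        assert v[0] == 1.0 and v.sum() == 1.0  # AA is index 0

    def test_gaac_group_counting(self):
        v = encode_composition_family(1, grouped=True, sequence="KRHDE")
        names = block_names(get_spec("GAAC"))
        d = dict(zip(names, v))
        assert d["GAAC.positivecharge"] == pytest.approx(0.6)
        assert d["GAAC.negativecharge"] == pytest.approx(0.4)
        assert d["GAAC.aliphatic"] == d["GAAC.aromatic"] == d["GAAC.uncharge"] == 0.0

    @given(seq=valid_sequences)
    @settings(max_examples=30, deadline=None)
    def test_composition_sums_to_one(self, seq):
        for order in (1, 2, 3):
            for grouped in (False, True):
                v = encode_composition_family(order, grouped, seq)
                assert abs(v.sum() - 1.0) < 1e-9

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="minimum"):
            encode_composition_family(3, False, "AA")


class TestKSpacedPairs:
    def test_k0_slice_equals_dpc(self, rng):
        seq = random_sequence(rng, 50)
        pairs = encode_kspaced_pairs(False, 2, seq)
        dpc = encode_composition_family(2, False, seq)
        np.testing.assert_allclose(pairs[:400], dpc)

    def test_gapped_pair_on_aca(self):
        v = encode_kspaced_pairs(False, 1, "ACA")
        k1 = v[400:]
        assert k1[0] == 1.0  # (A, _, A)
        assert k1.sum() == 1.0

    def test_homopolymer_all_slices_at_aa(self, rng):
        v = encode_kspaced_pairs(False, 3, "A" * 30)
        for k in range(4):
            s = v[k * 400 : (k + 1) * 400]
            assert s[0] == 1.0 and s.sum() == 1.0

    @given(seq=valid_sequences, k_max=st.integers(0, 4))
    @settings(max_examples=30, deadline=None)
    def test_each_slice_sums_to_one(self, seq, k_max):
        for grouped, unit in ((False, 400), (True, 25)):
            v = encode_kspaced_pairs(grouped, k_max, seq)
            for k in range(k_max + 1):
                assert abs(v[k * unit : (k + 1) * unit].sum() - 1.0) < 1e-9

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="minimum length is 7"):
            encode_kspaced_pairs(False, 5, "ACDEF")


class TestDDE:
    def test_mm_closed_form(self):
        # M has 1 codon: Dc(MM) = 1, Tm = (1/61)^2, Tv = Tm(1-Tm)/1
        v = encode_dde("MM")
        tm = (1 / 61) ** 2
        expected = (1 - tm) / np.sqrt(tm * (1 - tm) / 1)
        mm = 20 * AMINO_ACIDS.index("M") + AMINO_ACIDS.index("M")
        assert v[mm] == pytest.approx(expected)

    def test_absent_dipeptide_negative(self):
        v = encode_dde("A" * 30)
        # every dipeptide except AA is absent -> strictly negative
        assert (np.delete(v, 0) < 0).all() and v[0] > 0

    def test_dc_reconstruction_sums_to_one(self, rng):
        seq = random_sequence(rng, 45)
        n = len(seq)
        v = encode_dde(seq)
        p = np.array([CODON_COUNTS[a] for a in AMINO_ACIDS]) / 61
        tm = np.outer(p, p).ravel()
        tv = tm * (1 - tm) / (n - 1)
        dc = v * np.sqrt(tv) + tm
        assert dc.sum() == pytest.approx(1.0, abs=1e-9)


class TestCTD:
    def test_single_group_sequence(self):
        # all-A: per property, the group containing A gets composition 1
        vc = encode_ctd("C", "A" * 25)
        vt = encode_ctd("T", "A" * 25)
        assert np.all(vt == 0)
        for pi, (prop, groups) in enumerate(CTD_PROPERTIES.items()):
            triple = vc[3 * pi : 3 * pi + 3]
            g = next(i for i, members in enumerate(groups) if "A" in members)
            assert triple[g] == 1.0 and triple.sum() == 1.0

    def test_distribution_quantiles_homopolymer(self):
        v = encode_ctd("D", "A" * 20)
        names = block_names(get_spec("CTDD"))
        d = dict(zip(names, v))
        for prop, groups in CTD_PROPERTIES.items():
            g = next(i for i, members in enumerate(groups) if "A" in members) + 1
            got = [d[f"CTDD.{prop}.G{g}.p{q}"] for q in (0, 25, 50, 75, 100)]
            assert got == [5.0, 25.0, 50.0, 75.0, 100.0]

    def test_first_position_percentile(self):
        # charge property: K (G1) at position 1 of a length-100 sequence
        seq = "K" + "A" * 99
        v = encode_ctd("D", seq)
        names = block_names(get_spec("CTDD"))
        d = dict(zip(names, v))
        assert d["CTDD.charge.G1.p0"] == pytest.approx(1.0)

    def test_absent_group_zeroes(self):
        v = encode_ctd("D", "K" * 25)  # charge G3 (DE) absent
        names = block_names(get_spec("CTDD"))
        d = dict(zip(names, v))
        assert all(d[f"CTDD.charge.G3.p{q}"] == 0.0 for q in (0, 25, 50, 75, 100))

    def test_transition_fractions(self):
        # charge property on "KD": one adjacent pair, groups G1 vs G3
        v = encode_ctd("T", "KD")
        names = block_names(get_spec("CTDT"))
        d = dict(zip(names, v))
        assert d["CTDT.charge.G1G3"] == 1.0
        assert d["CTDT.charge.G1G2"] == 0.0

    def test_length_one_transition_raises(self):
        with pytest.raises(ValueError):
            encode_ctd("T", "A")


class TestCTriad:
    def test_single_class_sequence(self):
        v = encode_ctriad(0, "AGV" * 10)  # all residues in class 1
        assert v[0] == 1.0 and np.count_nonzero(v) == 1

    def test_ksctriad_k0_equals_ctriad(self, rng):
        seq = random_sequence(rng, 40)
        np.testing.assert_array_equal(encode_ctriad(0, seq), encode(get_spec("CTriad"), seq))

    def test_max_normalized(self, rng):
        v = encode_ctriad(2, random_sequence(rng, 50))
        for k in range(3):
            s = v[k * 343 : (k + 1) * 343]
            assert s.max() == pytest.approx(1.0)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="minimum length is 7"):
            encode_ctriad(2, "ACDEFG")


class TestNames:
    def test_gaac_names(self):
        assert block_names(get_spec("GAAC")) == (
            "GAAC.aliphatic", "GAAC.aromatic", "GAAC.positivecharge",
            "GAAC.negativecharge", "GAAC.uncharge",
        )

    def test_dpc_name_count_and_prefix(self):
        names = block_names(get_spec("DPC"))
        assert len(names) == 400
        assert names[0] == "DPC.AA" and all(n.startswith("DPC.") for n in names)

    def test_ctdc_contains_casg_hydrophobicity(self):
        assert "CTDC.hydrophobicity_CASG920101.G3" in block_names(get_spec("CTDC"))

    @pytest.mark.parametrize("name", DESCRIPTOR_NAMES)
    def test_names_unique_and_prefixed(self, name):
        spec = get_spec(name)
        names = block_names(spec)
        assert len(set(names)) == spec.dimension
        assert all(n.startswith(f"{name}.") for n in names)

    def test_composition_names_are_words(self):
        assert "TPC.KDL" in block_names(get_spec("TPC"))
        assert "AAC.P" in block_names(get_spec("AAC"))


def _brute_force_counts(seq, words, extractor):
    """Dictionary-based window enumeration, independent of the encoders."""
    counts = dict.fromkeys(words, 0)
    windows = extractor(seq)
    for w in windows:
        counts[w] += 1
    return np.array([counts[w] for w in words], dtype=float), len(windows)


class TestBruteForceOracle:
    """Explicit window enumeration equals encoder output exactly (len <= 30)."""

    def test_composition_and_gapped_counts(self, rng):
        group_of = {a: g for g, members in RESIDUE_GROUPS.items() for a in members}
        triad_of = {
            a: str(ci + 1)
            for ci, cls in enumerate(CONJOINT_TRIAD_CLASSES)
            for a in cls
        }
        aa = list(AMINO_ACIDS)
        groups = list(RESIDUE_GROUPS)
        for _ in range(15):
            seq = random_sequence(rng, int(rng.integers(20, 31)))
            n = len(seq)
            # plain and grouped compositions, order 1..3
            for order in (1, 2, 3):
                words = ["".join(w) for w in itertools.product(aa, repeat=order)]
                counts, m = _brute_force_counts(
                    seq, words, lambda s: [s[i : i + order] for i in range(len(s) - order + 1)]
                )
                np.testing.assert_allclose(
                    encode_composition_family(order, False, seq), counts / m, atol=1e-12
                )
                gwords = list(itertools.product(groups, repeat=order))
                gseq = [group_of[c] for c in seq]
                gcounts = dict.fromkeys(gwords, 0)
                for i in range(n - order + 1):
                    gcounts[tuple(gseq[i : i + order])] += 1
                np.testing.assert_allclose(
                    encode_composition_family(order, True, seq),
                    np.array([gcounts[w] for w in gwords]) / m,
                    atol=1e-12,
                )
            # k-spaced pairs, k_max = 3
            got = encode_kspaced_pairs(False, 3, seq)
            for k in range(4):
                words = ["".join(w) for w in itertools.product(aa, repeat=2)]
                pairs = [seq[i] + seq[i + k + 1] for i in range(n - k - 1)]
                counts = dict.fromkeys(words, 0)
                for p in pairs:
                    counts[p] += 1
                np.testing.assert_allclose(
                    got[k * 400 : (k + 1) * 400],
                    np.array([counts[w] for w in words]) / len(pairs),
                    atol=1e-12,
                )
            # conjoint triads, k_max = 1
            got = encode_ctriad(1, seq)
            tseq = [triad_of[c] for c in seq]
            for k in range(2):
                words = ["".join(w) for w in itertools.product("1234567", repeat=3)]
                triples = [
                    tseq[i] + tseq[i + k + 1] + tseq[i + 2 * k + 2]
                    for i in range(n - 2 * k - 2)
                ]
                counts = dict.fromkeys(words, 0)
                for t in triples:
                    counts[t] += 1
                arr = np.array([counts[w] for w in words], dtype=float)
                if arr.max() > 0:
                    arr /= arr.max()
                np.testing.assert_allclose(got[k * 343 : (k + 1) * 343], arr, atol=1e-12)

    def test_encoders_are_pure(self, rng):
        seq = random_sequence(rng, 30)
        for name in DESCRIPTOR_NAMES:
            spec = get_spec(name)
            np.testing.assert_array_equal(encode(spec, seq), encode(spec, seq))
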