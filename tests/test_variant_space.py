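"""Degenerate-codon genetics, space counting, coverage and sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from armlearn.variant_space import (
    AMINO_ACIDS,
    CodonScheme,
    VariantSpace,
    count_constrained_library,
    enumerate_constrained,
    enumerate_space,
    expand_degenerate_codon,
    expected_coverage,
    full_coverage_probability,
    hamming_distance,
    sample_constrained,
    sample_randomization,
    variant_space_size,
)


@pytest.mark.parametrize(
    "codon, n_codons, n_aas, n_stops",
    [
        ("NDT", 12, 12, 0),
        ("NNK", 32, 20, 1),
        ("NNN", 64, 20, 3),
        ("TTT", 1, 1, 0),
    ],
)
def test_degenerate_codon_expansion_counts(codon, n_codons, n_aas, n_stops):
    exp = expand_degenerate_codon(codon)
    assert exp.n_codons == n_codons
    assert len(exp.amino_acids) == n_aas
    assert exp.n_stop_codons == n_stops


def test_ndt_encodes_the_twelve_chemical_classes():
    exp = expand_degenerate_codon("NDT")
    assert exp.amino_acids == frozenset("NSIHRLDGVYCF")


def test_nnk_single_stop_is_amber():
    exp = expand_degenerate_codon("NNK")
    stops = [c for c, aa in exp.translation.items() if aa == "*"]
    assert stops == ["TAG"]


def test_nnk_residue_weights_are_codon_proportional():
    weights = expand_degenerate_codon("NNK").residue_weights()
    # Serine has three NNK codons (AGT, TCG, TCT) of 31 sense codons.
    assert weights["S"] == pytest.approx(3 / 31)
    assert sum(weights.values()) == pytest.approx(1.0)


def test_invalid_iupac_letter_is_reported():
    with pytest.raises(ValueError, match="Z"):
        CodonScheme("NZT")


def test_variant_space_sizes(space):
    assert variant_space_size(space) == 3_200_000
    twelve = VariantSpace(positions=(1,), reference="A", wild_type="C", alphabet="ACDEFGHIKLMN")
    assert variant_space_size(twelve) == 12
    empty = VariantSpace(positions=(), reference="", wild_type="")
    assert variant_space_size(empty) == 1


def test_space_invariants_enforced():
    with pytest.raises(ValueError):
        VariantSpace(positions=(2, 1), reference="AA", wild_type="AA")
    with pytest.raises(ValueError):
        VariantSpace(positions=(1, 2), reference="A", wild_type="AA")
    with pytest.raises(ValueError):
        VariantSpace(positions=(1,), reference="B", wild_type="A")


def test_hamming_examples():
    assert hamming_distance("TFNAQ", "TFNAQ") == 0
    # Reference is the S112F K121Q double mutant of the wild type.
    assert hamming_distance("TSNAK", "TFNAQ") == 2
    assert hamming_distance("TFNAQ", "CTNLV") == 4
    with pytest.raises(ValueError):
        hamming_distance("TFNAQ", "TFNA")


@settings(max_examples=100, derandomize=True)
@given(st.data())
def test_hamming_metric_axioms(data):
    codes = st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=5)
    a, b, c = (data.draw(codes) for _ in range(3))
    assert hamming_distance(a, a) == 0
    assert hamming_distance(a, b) == hamming_distance(b, a)
    assert hamming_distance(a, c) <= hamming_distance(a, b) + hamming_distance(b, c)
    assert (hamming_distance(a, b) == 0) == (a == b)


def test_expected_coverage_at_design_point_matches_monte_carlo():
    analytic = expected_coverage(36, 12)
    rng = np.random.default_rng(42)
    draws = rng.integers(12, size=(20_000, 36))
    mc = np.mean([np.unique(row).size for row in draws]) / 12
    assert analytic == pytest.approx(0.9564, abs=1e-3)
    assert analytic == pytest.approx(mc, abs=3e-3)


def test_expected_coverage_edge_cases():
    assert expected_coverage(0, 12) == 0.0
    assert expected_coverage(1, 1) == 1.0
    with pytest.raises(ValueError):
        expected_coverage(10, 0)


@settings(max_examples=60, derandomize=True)
@given(n=st.integers(0, 500), v=st.integers(1, 100))
def test_expected_coverage_bounds_and_monotonicity(n, v):
    cov = expected_coverage(n, v)
    assert 0.0 <= cov <= 1.0
    assert expected_coverage(n + 1, v) >= cov
    assert full_coverage_probability(n, v) <= cov + 1e-12


def test_constrained_library_counts(space):
    assert count_constrained_library(space, 5) == variant_space_size(space)
    assert count_constrained_library(space, 0) == 1
    assert count_constrained_library(space, 4) == 723_901
    with pytest.raises(ValueError):
        count_constrained_library(space, 6)


def test_constrained_enumeration_matches_brute_force(toy_space):
    for m in range(4):
        brute = {
            "".join(t)
            for t in itertools.product(toy_space.alphabet, repeat=3)
            if hamming_distance("".join(t), toy_space.reference) <= m
        }
        enumerated = list(enumerate_constrained(toy_space, m))
        assert len(enumerated) == len(set(enumerated)) == count_constrained_library(toy_space, m)
        assert set(enumerated) == brute


def test_sample_constrained_respects_load_distribution(space, rng):
    codes = sample_constrained(space, 200, {2: 0.5, 4: 0.5}, rng)
    loads = {hamming_distance(c, space.reference) for c in codes}
    assert loads <= {2, 4}
    assert len(codes) == 200


def test_sample_randomization_ndt_is_codon_uniform(space):
    df = sample_randomization(space, "NDT", [111], 6000, rng=1)
    residues = df["variant_code"].str[0]
    counts = residues.value_counts()
    assert set(counts.index) <= set("NSIHRLDGVYCF") | {"T"}
    # All 12 NDT residues equiprobable at 1/12 each.
    observed = [counts.get(aa, 0) for aa in "NSIHRLDGVYCF"]
    assert stats.chisquare(observed).pvalue > 1e-3
    assert not df["nonsense"].any()


def test_sample_randomization_flags_nnk_stops(space):
    df = sample_randomization(space, "NNK", list(space.positions), 2000, rng=2)
    assert df["nonsense"].any()
    assert (df.loc[df["nonsense"], "variant_code"].str.contains("\\*")).all()


def test_sample_randomization_edge_cases(space):
    assert len(sample_randomization(space, "NDT", [111], 0, rng=0)) == 0
    with pytest.warns(UserWarning):
        df = sample_randomization(space, "NDT", [], 3, rng=0)
    assert (df["variant_code"] == space.reference).all()
    with pytest.raises(ValueError):
        sample_randomization(space, "NDT", [999], 1, rng=0)


def test_enumerate_space_streams_all_variants(toy_space):
    chunks = list(enumerate_space(toy_space, chunk_size=7))
    flat = [c for chunk in chunks for c in chunk]
    assert len(flat) == variant_space_size(toy_space) == 64
    assert len(set(flat)) == 64
    assert all(len(chunk) <= 7 for chunk in chunks)
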