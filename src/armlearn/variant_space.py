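"""Combinatorial variant spaces, degenerate-codon genetics and library design.

A protein engineering campaign over a handful of randomized residues works
on five-letter (more generally, P-letter) amino-acid codes: the residue
identities at the randomized positions, everything else held at the parent
sequence.  This module defines that search space, the degenerate codons
(NDT, NNK, ...) used to build physical libraries in it, Hamming geometry,
and the counting/sampling utilities needed for library design: statistical
coverage of a randomization, mutational-load-constrained sub-libraries, and
codon-usage-weighted sampling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "AMINO_ACIDS",
    "VariantSpace",
    "CodonScheme",
    "CodonExpansion",
    "expand_degenerate_codon",
    "variant_space_size",
    "hamming_distance",
    "expected_coverage",
    "full_coverage_probability",
    "count_constrained_library",
    "enumerate_constrained",
    "sample_constrained",
    "sample_randomization",
    "enumerate_space",
]

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Codon -> amino acid for the 61 sense codons of the standard genetic code.
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class VariantSpace:
    """The combinatorial search space over a set of randomized residues.

    Parameters
    ----------
    positions
        Residue indices in the parent protein, strictly increasing
        (e.g. ``(111, 112, 118, 119, 121)`` for the streptavidin scaffold).
    reference
        Amino-acid letters of the reference (parent) variant at those
        positions; activities are reported relative to this variant.
    wild_type
        Amino-acid letters of the wild-type protein at those positions.
    alphabet
        Allowed letters, by default the 20 canonical amino acids.
    """

    positions: tuple[int, ...]
    reference: str
    wild_type: str
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "reference", self.reference.upper())
        object.__setattr__(self, "wild_type", self.wild_type.upper())
        if not all(a < b for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for name in ("reference", "wild_type"):
            code = getattr(self, name)
            if len(code) != len(self.positions):
                raise ValueError(
                    f"{name} length {len(code)} != number of positions "
                    f"{len(self.positions)}"
                )
            bad = set(code) - set(self.alphabet)
            if bad:
                raise ValueError(f"{name} contains letters outside alphabet: {sorted(bad)}")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def size(self) -> int:
        return variant_space_size(self)

    def validate_variant(self, code: str) -> str:
        """Canonicalize a variant code (upper-case) and check it belongs here."""
        code = code.upper()
        if len(code) != self.n_positions:
            raise ValueError(
                f"variant {code!r} has length {len(code)}, expected {self.n_positions}"
            )
        bad = set(code) - set(self.alphabet)
        if bad:
            raise ValueError(f"variant {code!r} contains letters outside alphabet: {sorted(bad)}")
        return code

    def mutational_load(self, code: str) -> int:
        """Number of substitutions of ``code`` relative to the reference."""
        return hamming_distance(self.validate_variant(code), self.reference)


def sav_space() -> VariantSpace:
    """The five-position streptavidin space used throughout the examples.

    Positions 111/112/118/119/121, reference TFNAQ (the S112F K121Q double
    mutant) and wild type TSNAK.
    """
    return VariantSpace(
        positions=(111, 112, 118, 119, 121), reference="TFNAQ", wild_type="TSNAK"
    )


__all__.append("sav_space")


@dataclass(frozen=True)
class CodonExpansion:
    """Concrete expansion of a degenerate codon under the standard code."""

    codons: tuple[str, ...]
    translation: dict[str, str] = field(repr=False)  # codon -> amino acid or "*"
    amino_acids: frozenset[str]
    n_stop_codons: int

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def residue_weights(self, include_stop: bool = False) -> dict[str, float]:
        """Codon-proportional residue probabilities.

        Matches physical library construction: NNK encodes serine with three
        codons out of 32, so its weight is 3/32, not 1/21.
        """
        counts: dict[str, int] = {}
        for codon in self.codons:
            aa = self.translation[codon]
            if aa == "*" and not include_stop:
                continue
            counts[aa] = counts.get(aa, 0) + 1
        total = len(self.codons) if include_stop else sum(counts.values())
        return {aa: c / total for aa, c in sorted(counts.items())}


@dataclass(frozen=True)
class CodonScheme:
    """A degenerate codon (IUPAC letters) interpreted under the standard code."""

    degenerate_codon: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "degenerate_codon", self.degenerate_codon.upper())
        if len(self.degenerate_codon) != 3:
            raise ValueError(f"degenerate codon must have 3 letters: {self.degenerate_codon!r}")
        for ch in self.degenerate_codon:
            if ch not in ambiguous_dna_values:
                raise ValueError(f"invalid IUPAC nucleotide code {ch!r} in {self.degenerate_codon!r}")

    def expand(self) -> CodonExpansion:
        return expand_degenerate_codon(self)


def expand_degenerate_codon(scheme: CodonScheme | str) -> CodonExpansion:
    """Enumerate every concrete codon matching a degenerate codon.

    Returns the codon set, the codon->residue translation (stops as ``"*"``)
    and summary counts.  NDT expands to 12 codons encoding 12 distinct amino
    acids with no stops; NNK to 32 codons, all 20 amino acids and one stop
    (TAG).
    """
    if isinstance(scheme, str):
        scheme = CodonScheme(scheme)
    bases = [ambiguous_dna_values[ch] for ch in scheme.degenerate_codon]
    codons = tuple("".join(c) for c in itertools.product(*bases))
    translation = {c: GENETIC_CODE.get(c, "*") for c in codons}
    aas = frozenset(aa for aa in translation.values() if aa != "*")
    n_stop = sum(1 for aa in translation.values() if aa == "*")
    return CodonExpansion(codons=codons, translation=translation, amino_acids=aas, n_stop_codons=n_stop)


def variant_space_size(space: VariantSpace) -> int:
    """|alphabet| ** |positions|; 20**5 = 3,200,000 for the five-site space."""
    return len(space.alphabet) ** space.n_positions


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two variant codes differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


def expected_coverage(n_clones: int, n_outcomes: int) -> float:
    """Expected fraction of distinct outcomes seen in ``n_clones`` draws.

    For V equiprobable outcomes the expected coverage of N i.i.d. draws is
    ``1 - (1 - 1/V)**N``.  Screening 36 clones over an NDT codon (12
    outcomes) gives ~95.6% coverage, the usual "~95%" design point.
    """
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    return 1.0 - (1.0 - 1.0 / n_outcomes) ** n_clones


def full_coverage_probability(n_clones: int, n_outcomes: int) -> float:
    """P(all V outcomes observed at least once) by inclusion-exclusion."""
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    V = n_outcomes
    # Exact integer arithmetic: the alternating binomial sum cancels
    # catastrophically in floating point for large V.
    total = sum((-1) ** j * math.comb(V, j) * (V - j) ** n_clones for j in range(V + 1))
    return float(total / V**n_clones)


def count_constrained_library(space: VariantSpace, max_substitutions: int) -> int:
    """Number of variants with at most ``max_substitutions`` vs the reference.

    Closed form ``sum_k C(P, k) * (A-1)**k``; with 5 positions, 20 letters
    and a load cap of 4 this is 723,901 of the full 3,200,000.
    """
    P = space.n_positions
    if not 0 <= max_substitutions <= P:
        raise ValueError(f"max_substitutions must be in [0, {P}], got {max_substitutions}")
    A = len(space.alphabet)
    return sum(math.comb(P, k) * (A - 1) ** k for k in range(max_substitutions + 1))


def enumerate_constrained(space: VariantSpace, max_substitutions: int) -> Iterator[str]:
    """Yield every variant within the mutational-load constraint, reference first."""
    P = space.n_positions
    if not 0 <= max_substitutions <= P:
        raise ValueError(f"max_substitutions must be in [0, {P}], got {max_substitutions}")
    ref = space.reference
    alt = {i: [a for a in space.alphabet if a != ref[i]] for i in range(P)}
    for k in range(max_substitutions + 1):
        for sites in itertools.combinations(range(P), k):
            for letters in itertools.product(*(alt[i] for i in sites)):
                code = list(ref)
                for i, aa in zip(sites, letters):
                    code[i] = aa
                yield "".join(code)


def sample_constrained(
    space: VariantSpace,
    n: int,
    load_distribution: dict[int, float],
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Draw variants with mutational load sampled from ``load_distribution``.

    Within a load k, the k mutated sites and the substituting letters are
    uniform.  Used to emulate a library built from mixed sublibraries with
    different numbers of randomized positions.
    """
    rng = np.random.default_rng(rng)
    loads = sorted(load_distribution)
    if any(not 0 <= k <= space.n_positions for k in loads):
        raise ValueError("loads must be within [0, n_positions]")
    probs = np.array([load_distribution[k] for k in loads], dtype=float)
    probs = probs / probs.sum()
    ref = space.reference
    out: list[str] = []
    for _ in range(n):
        k = int(rng.choice(loads, p=probs))
        sites = rng.choice(space.n_positions, size=k, replace=False)
        code = list(ref)
        for i in sites:
            choices = [a for a in space.alphabet if a != ref[i]]
            code[i] = choices[int(rng.integers(len(choices)))]
        out.append("".join(code))
    return out


def sample_randomization(
    space: VariantSpace,
    scheme: CodonScheme | str,
    positions_randomized: Sequence[int],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate cloning ``n`` variants with a degenerate codon at a site subset.

    Randomized positions draw residues codon-proportionally from the scheme
    (stop codons yield a ``"*"`` letter and a nonsense flag); remaining
    positions stay at the reference.  Returns a DataFrame with columns
    ``variant_code`` and ``nonsense``.
    """
    bad = set(positions_randomized) - set(space.positions)
    if bad:
        raise ValueError(f"positions not in space: {sorted(bad)}")
    rng = np.random.default_rng(rng)
    if n == 0:
        return pd.DataFrame({"variant_code": pd.Series([], dtype=str), "nonsense": pd.Series([], dtype=bool)})
    if len(positions_randomized) == 0:
        warnings.warn("no positions randomized; returning copies of the reference")
        return pd.DataFrame({"variant_code": [space.reference] * n, "nonsense": [False] * n})
    expansion = expand_degenerate_codon(scheme)
    weights = expansion.residue_weights(include_stop=True)
    residues = list(weights)
    probs = np.array([weights[r] for r in residues])
    idx = {p: i for i, p in enumerate(space.positions)}
    rand_idx = [idx[p] for p in positions_randomized]
    codes: list[str] = []
    nonsense: list[bool] = []
    for _ in range(n):
        code = list(space.reference)
        for i in rand_idx:
            code[i] = residues[int(rng.choice(len(residues), p=probs))]
        s = "".join(code)
        codes.append(s)
        nonsense.append("*" in s)
    return pd.DataFrame({"variant_code": codes, "nonsense": nonsense})


def enumerate_space(space: VariantSpace, chunk_size: int = 100_000) -> Iterator[list[str]]:
    """Stream the full variant space in lexicographic chunks.

    Constant memory per chunk, so the full 3.2M-variant space can be scanned
    for model scoring without materializing it.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    it = itertools.product(space.alphabet, repeat=space.n_positions)
    while True:
        chunk = ["".join(t) for t in itertools.islice(it, chunk_size)]
        if not chunk:
            return
        yield chunk
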