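"""Ground-truth landscape simulator and fixture generators.

Every pipeline stage is testable against simulated data that emulates the
study conditions: a five-position variant space whose log-activity is the
sum of a baseline, per-position additive residue effects, and sparse
pairwise epistatic interactions; a probability of complete inactivation
that grows with mutational load (so most quintuple mutants sit at the
background level); and multiplicative (log-additive) measurement noise of
constant variance.  Effects are zero for the reference residues, so the
reference variant has relative activity 1 by construction and "hit" keeps
its meaning of beating the reference.

The same module generates paired-FASTQ fixtures carrying the barcode layout
of :mod:`armlearn.ngs_demux`, including per-base substitution errors and
PCR-chimera reads, together with a ground-truth manifest.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .measurements import EV_LABEL, REF_LABEL
from .ngs_demux import ROW_NAMES, BarcodeScheme
from .variant_space import VariantSpace, sample_constrained

__all__ = [
    "LandscapeModel",
    "CampaignConfig",
    "CampaignResult",
    "simulate_landscape",
    "measure",
    "simulate_campaign",
    "generate_fastq_fixture",
]

#: Preferred E. coli codon per amino acid (plus amber stop for building
#: deliberate nonsense fixtures), used for reverse translation.
PREFERRED_CODON = {
    "*": "TAG",
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass
class LandscapeModel:
    """Deterministic ground-truth log-activity function with noise parameters.

    ``log_activity(code)`` = mu + sum_i additive[i][aa] + sum_{i<j}
    epistatic[(i,j)][(aa_i, aa_j)] for live variants, or the background log
    level for inactivated variants.  Inactivation follows a stability
    threshold: every non-reference residue carries a nonnegative
    destabilization cost, and a variant whose summed cost exceeds
    ``stability_threshold`` is dead.  Because costs add, the fraction of
    dead variants grows with mutational load, while deadness remains a
    deterministic, learnable function of the genotype.
    """

    space: VariantSpace
    mu: float
    additive: list[dict[str, float]]
    epistatic: dict[tuple[int, int], dict[tuple[str, str], float]]
    destabilization: list[dict[str, float]]
    stability_threshold: float
    background: float
    sigma_log: float
    seed: int

    @property
    def background_log(self) -> float:
        return float(np.log(self.background))

    def destabilization_cost(self, code: str) -> float:
        code = self.space.validate_variant(code)
        return float(sum(self.destabilization[i].get(aa, 0.0) for i, aa in enumerate(code)))

    def is_dead(self, code: str) -> bool:
        return self.destabilization_cost(code) > self.stability_threshold

    def genotype_effect(self, code: str) -> float:
        """The additive + epistatic log-activity, ignoring inactivation."""
        code = self.space.validate_variant(code)
        total = self.mu
        for i, aa in enumerate(code):
            total += self.additive[i].get(aa, 0.0)
        for (i, j), table in self.epistatic.items():
            total += table.get((code[i], code[j]), 0.0)
        return total

    def log_activity(self, code: str) -> float:
        if self.is_dead(code):
            return self.background_log
        return self.genotype_effect(code)

    def log_activities(self, codes: Iterable[str]) -> np.ndarray:
        return np.array([self.log_activity(c) for c in codes])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positions": list(self.space.positions),
            "reference": self.space.reference,
            "wild_type": self.space.wild_type,
            "mu": self.mu,
            "additive": [{aa: v for aa, v in d.items()} for d in self.additive],
            "epistatic": {
                f"{i},{j}": {f"{a}{b}": v for (a, b), v in tbl.items()}
                for (i, j), tbl in self.epistatic.items()
            },
            "destabilization": [{aa: v for aa, v in d.items()} for d in self.destabilization],
            "stability_threshold": self.stability_threshold,
            "background": self.background,
            "sigma_log": self.sigma_log,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandscapeModel":
        d = json.loads(Path(path).read_text())
        space = VariantSpace(tuple(d["positions"]), d["reference"], d["wild_type"])
        epistatic = {
            tuple(int(x) for x in key.split(",")): {
                (combo[0], combo[1]): v for combo, v in tbl.items()
            }
            for key, tbl in d["epistatic"].items()
        }
        return cls(
            space=space,
            mu=d["mu"],
            additive=[dict(t) for t in d["additive"]],
            epistatic=epistatic,
            destabilization=[dict(t) for t in d["destabilization"]],
            stability_threshold=d["stability_threshold"],
            background=d["background"],
            sigma_log=d["sigma_log"],
            seed=d["seed"],
        )


def simulate_landscape(
    space: VariantSpace,
    additive_scale: float = 0.4,
    additive_mean: float = -0.35,
    epistasis_density: float = 0.3,
    epistasis_scale: float = 0.3,
    destabilization_scale: float = 1.0,
    stability_threshold: float = 4.0,
    background: float = 0.05,
    sigma_log: float = 0.3,
    seed: int = 0,
    planted_optimum: str | None = None,
) -> LandscapeModel:
    """Draw a rugged epistatic landscape with load-dependent inactivation.

    Additive residue effects are Normal(additive_mean, additive_scale^2) —
    the negative mean makes most substitutions deleterious, so only a few
    percent of random triple/quadruple mutants beat the reference, as in
    real saturation libraries.  Each position pair carries an epistatic
    table with probability ``epistasis_density``; its entries are
    heavy-tailed Laplace(0, epistasis_scale) draws for a random quarter of
    the residue combinations.  Per-residue destabilization costs are
    Exponential(destabilization_scale); with the default threshold of 4 the
    dead fraction rises from ~10% of double mutants to ~60-70% of quintuple
    mutants, emulating the marked activity drop at high mutational load.
    Reference residues have zero effects and zero cost, so the reference
    sits at relative activity 1.  ``planted_optimum`` optionally boosts one
    known variant to a clear global optimum for discovery-rate studies.
    """
    if not 0.0 <= epistasis_density <= 1.0:
        raise ValueError("epistasis_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    P = space.n_positions
    additive: list[dict[str, float]] = []
    for i in range(P):
        effects = {}
        for aa in space.alphabet:
            if aa == space.reference[i]:
                continue
            effects[aa] = float(rng.normal(additive_mean, additive_scale))
        additive.append(effects)
    epistatic: dict[tuple[int, int], dict[tuple[str, str], float]] = {}
    for i in range(P):
        for j in range(i + 1, P):
            if rng.random() >= epistasis_density:
                continue
            table: dict[tuple[str, str], float] = {}
            for a in space.alphabet:
                for b in space.alphabet:
                    if a == space.reference[i] or b == space.reference[j]:
                        continue
                    if rng.random() < 0.25:
                        table[(a, b)] = float(rng.laplace(0.0, epistasis_scale))
            if table:
                epistatic[(i, j)] = table
    destabilization: list[dict[str, float]] = []
    for i in range(P):
        costs = {}
        for aa in space.alphabet:
            if aa == space.reference[i]:
                continue
            costs[aa] = float(rng.exponential(destabilization_scale))
        destabilization.append(costs)
    model = LandscapeModel(
        space=space,
        mu=0.0,
        additive=additive,
        epistatic=epistatic,
        destabilization=destabilization,
        stability_threshold=stability_threshold,
        background=background,
        sigma_log=sigma_log,
        seed=seed,
    )
    if planted_optimum is not None:
        code = space.validate_variant(planted_optimum)
        # Keep the planted variant alive and lift it clearly above the reference.
        for i, aa in enumerate(code):
            if aa != space.reference[i]:
                destabilization[i][aa] = min(
                    destabilization[i][aa], stability_threshold / (2 * P)
                )
        current = model.genotype_effect(code)
        pair = (0, 1)
        epistatic.setdefault(pair, {})[(code[0], code[1])] = (
            epistatic.get(pair, {}).get((code[0], code[1]), 0.0) + max(0.0, -current) + 1.5
        )
    return model


def measure(
    landscape: LandscapeModel,
    codes: Sequence[str],
    n_replicates: int = 1,
    seed: int = 0,
    plate_effect_sd: float = 0.1,
    wells_per_plate: int = 90,
    raw_scale: float = 2.0,
) -> pd.DataFrame:
    """Simulate a plate screen of the given variants.

    Variants (each measured ``n_replicates`` times) are laid out on 96-well
    plates with triplicate reference and empty-vector controls per plate.
    Observed log activity is f(v) + eps with eps ~ Normal(0, sigma_log^2)
    i.i.d.; raw activities additionally carry a per-plate multiplicative
    effect that plate normalization must remove.  Returns the raw
    measurement table (plate_id, well_id, label, raw_activity).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = landscape.sigma_log
    entries = [c for c in codes for _ in range(n_replicates)]
    rows = []
    plate = 0
    for start in range(0, len(entries), wells_per_plate):
        plate += 1
        plate_factor = float(np.exp(rng.normal(0.0, plate_effect_sd)))
        chunk = entries[start : start + wells_per_plate]
        well = 0
        labels = chunk + [REF_LABEL] * 3 + [EV_LABEL] * 3
        for label in labels:
            well += 1
            well_id = f"{ROW_NAMES[(well - 1) // 12]}{(well - 1) % 12 + 1:02d}"
            if label == REF_LABEL:
                log_a = 0.0
            elif label == EV_LABEL:
                log_a = landscape.background_log
            else:
                log_a = landscape.log_activity(label)
            noisy = log_a + rng.normal(0.0, sigma)
            rows.append(
                {
                    "plate_id": plate,
                    "well_id": well_id,
                    "label": label,
                    "raw_activity": raw_scale * plate_factor * float(np.exp(noisy)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CampaignConfig:
    """Knobs of a simulated three-round campaign."""

    round_sizes: tuple[int, int, int] = (96, 64, 64)
    load_distribution: tuple[tuple[int, float], ...] = ((3, 0.5), (4, 0.5))
    replicate_fraction: float = 0.15
    candidate_pool_size: int = 1500
    # At desk scale the candidate pool is ~2000x smaller than the full space,
    # so the high-prediction pool fed to the DPP is kept at 2x the batch size
    # (5x would reach far down the pool's quantiles and dilute exploitation).
    exploit_pool_factor: int = 2
    kernel: str = "matern52"
    n_restarts: int = 2
    log_floor: float = 0.01
    hit_threshold: float = 1.0


@dataclass
class CampaignResult:
    """Per-round tables, hit rates and selected batches of a campaign."""

    rounds: list[dict] = field(default_factory=list)

    @property
    def hit_rates(self) -> list[float]:
        return [r["hit_rate"] for r in self.rounds]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "round": i + 1,
                    "strategy": r["strategy"],
                    "n_variants": r["n_variants"],
                    "hit_rate": r["hit_rate"],
                    "max_relative_activity": r["max_relative_activity"],
                }
                for i, r in enumerate(self.rounds)
            ]
        )


def _round_metrics(table: pd.DataFrame, threshold: float) -> dict:
    from .active_learning import hit_rate
    from .measurements import training_rows

    tr = training_rows(table)
    per_variant = tr.groupby("label")["relative_activity"].mean()
    return {
        "n_variants": int(per_variant.size),
        "hit_rate": hit_rate(per_variant.to_numpy(), threshold),
        "max_relative_activity": float(per_variant.max()),
    }


def simulate_campaign(
    landscape: LandscapeModel,
    config: CampaignConfig | None = None,
    strategy: str = "active",
    seed: int = 0,
    property_table=None,
) -> CampaignResult:
    """Run a three-round in-silico campaign on a synthetic landscape.

    Round 1 screens a mutational-load-constrained random library (with a
    replicated subset for noise estimation).  Under ``strategy="active"``,
    round 2 is an uncertainty-driven exploration batch and round 3 a
    DPP-diversified exploitation batch, both selected from a seeded random
    candidate pool of the full space; ``"greedy"`` replaces both model
    rounds with top-mean selection (no diversification), and ``"random"``
    draws every round at random — the no-model control.
    """
    from .active_learning import select_exploitation_batch, select_exploration_batch
    from .encoding import PropertyTable, encode_variants, standardize
    from .gp_model import GPConfig, fit_gp
    from .measurements import (
        estimate_noise,
        log_transform,
        normalize_to_reference,
        training_rows,
    )

    if strategy not in ("active", "random", "greedy"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if config is None:
        config = CampaignConfig()
    if property_table is None:
        property_table = PropertyTable.default()
    space = landscape.space
    rng = np.random.default_rng(seed)
    result = CampaignResult()

    # --- Round 1: load-constrained random library with a replicated subset.
    n1 = config.round_sizes[0]
    load_dist = dict(config.load_distribution)
    codes1 = sample_constrained(space, n1, load_dist, rng)
    n_rep = max(int(round(config.replicate_fraction * n1)), 1)
    replicated = list(dict.fromkeys(codes1))[:n_rep]
    screened = codes1 + replicated
    table = measure(landscape, screened, seed=int(rng.integers(2**31)))
    table = log_transform(normalize_to_reference(table), floor=config.log_floor)
    table["round_id"] = 1
    result.rounds.append(
        {"strategy": strategy, "table": table, "batch": None, **_round_metrics(table, config.hit_threshold)}
    )

    tested: set[str] = set(codes1)
    all_tables = [table]

    for round_no, n_batch in zip((2, 3), config.round_sizes[1:]):
        data = pd.concat(all_tables, ignore_index=True)
        tr = training_rows(data)
        if strategy == "random":
            batch_codes = sample_constrained(space, n_batch, {5: 1.0}, rng)
            batch = None
        else:
            noise = estimate_noise(data)
            fm = encode_variants(tr["label"].tolist(), property_table, space)
            fm = standardize(fm)
            gp_cfg = GPConfig(
                kernel=config.kernel,
                sigma_log=noise.sigma_log,
                n_restarts=config.n_restarts,
                seed=int(rng.integers(2**31)),
            )
            fit = fit_gp(fm.X, tr["log_activity"].to_numpy(), gp_cfg)
            # Candidate pool: seeded draw stratified over mutational load so
            # the pool, like a full-space scan, contains candidates at every
            # distance from the reference; tested variants are excluded.
            pool_loads = {k: 1.0 for k in range(1, space.n_positions + 1)}
            pool_codes: list[str] = []
            seen = set(tested)
            while len(pool_codes) < config.candidate_pool_size:
                for c in sample_constrained(
                    space, config.candidate_pool_size, pool_loads, rng
                ):
                    if c not in seen:
                        seen.add(c)
                        pool_codes.append(c)
                        if len(pool_codes) == config.candidate_pool_size:
                            break
            fm_pool = encode_variants(pool_codes, property_table, space)
            fm_pool = standardize(fm_pool, fit=False, stats=(fm.center, fm.scale))
            if strategy == "active" and round_no == 2:
                batch = select_exploration_batch(
                    fit, fm_pool.X, pool_codes, n_batch, round_label=str(round_no)
                )
            elif strategy == "greedy" or (strategy == "active" and round_no == 3):
                pool_size = (
                    n_batch if strategy == "greedy" else config.exploit_pool_factor * n_batch
                )
                batch = select_exploitation_batch(
                    fit,
                    fm_pool.X,
                    pool_codes,
                    n_batch,
                    pool_size=pool_size,
                    round_label=str(round_no),
                )
            batch_codes = batch.variants
        tbl = measure(landscape, list(batch_codes), seed=int(rng.integers(2**31)))
        tbl = log_transform(normalize_to_reference(tbl), floor=config.log_floor)
        tbl["round_id"] = round_no
        result.rounds.append(
            {"strategy": strategy, "table": tbl, "batch": batch, **_round_metrics(tbl, config.hit_threshold)}
        )
        tested.update(batch_codes)
        all_tables.append(tbl)
    return result


# ---------------------------------------------------------------------------
# FASTQ fixtures
# ---------------------------------------------------------------------------


def _reverse_translate(code: str, rng: np.random.Generator | None = None) -> tuple[str, ...]:
    return tuple(PREFERRED_CODON[aa] for aa in code)


def _build_read_pair(
    plate: int,
    row_idx: int,
    col_idx: int,
    codons: tuple[str, ...],
    scheme: BarcodeScheme,
    rng: np.random.Generator,
) -> tuple[str, str]:
    pf_idx, pr_idx = scheme.plate_indices(plate)
    fillers = "ACGT"

    def render(segments, values) -> str:
        out = []
        for name, n in segments:
            if name == "const":
                filler_rng = np.random.default_rng(zlib.crc32(f"const:{name}:{n}".encode()))
                out.append("".join(fillers[i] for i in filler_rng.integers(4, size=n)))
            else:
                out.append(values[name])
        return "".join(out)

    values1 = {
        "plate_fwd": scheme.plate_fwd_barcodes[pf_idx],
        "row": scheme.row_barcodes[row_idx],
    }
    values2 = {
        "plate_rev": scheme.plate_rev_barcodes[pr_idx],
        "col": scheme.col_barcodes[col_idx],
    }
    for i, codon in enumerate(codons):
        values2[f"codon{i}"] = codon
    return render(scheme.layout.read1, values1), render(scheme.layout.read2, values2)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for i in range(len(arr)):
        if rng.random() < error_rate:
            arr[i] = "ACGT"[int(rng.integers(4))]
    return "".join(arr)


def generate_fastq_fixture(
    plate_map: dict[tuple[int, str], str | list[str]],
    scheme: BarcodeScheme,
    out_dir: str | Path,
    reads_per_well: int = 50,
    error_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write a paired FASTQ fixture plus ground-truth manifest.

    ``plate_map`` maps (plate_id, well_id) to a variant code or a list of
    codes (a multi-variant well).  Each read draws its template uniformly
    from the well's variants, applies i.i.d. substitution errors at
    ``error_rate``, and with probability ``chimera_rate`` splices the codon
    prefix of one template onto the codon suffix of another (PCR-mediated
    recombination; chimeras of identical parents are identical to them).
    """
    if reads_per_well < 1:
        raise ValueError("reads_per_well must be >= 1")
    for rate, name in ((error_rate, "error_rate"), (chimera_rate, "chimera_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"reads_R1{suffix}"
    r2_path = out_dir / f"reads_R2{suffix}"
    manifest_path = out_dir / "manifest.csv"

    opener = (lambda p: gzip.open(p, "wt")) if gzip_output else (lambda p: open(p, "w"))
    manifest_rows = []
    row_index = {r: i for i, r in enumerate(ROW_NAMES)}
    with opener(r1_path) as f1, opener(r2_path) as f2:
        read_no = 0
        for (plate, well), variants in sorted(plate_map.items()):
            if isinstance(variants, str):
                variants = [variants]
            codon_sets = [_reverse_translate(v) for v in variants]
            row_idx = row_index[well[0]]
            col_idx = int(well[1:]) - 1
            manifest_rows.append(
                {"plate_id": plate, "well_id": well, "true_variants": "|".join(variants)}
            )
            for _ in range(reads_per_well):
                read_no += 1
                codons = list(codon_sets[int(rng.integers(len(codon_sets)))])
                if chimera_rate > 0 and rng.random() < chimera_rate:
                    other = codon_sets[int(rng.integers(len(codon_sets)))]
                    cut = int(rng.integers(1, len(codons)))
                    codons = list(codons[:cut]) + list(other[cut:])
                s1, s2 = _build_read_pair(
                    plate, row_idx, col_idx, tuple(codons), scheme, rng
                )
                s1 = _mutate(s1, error_rate, rng)
                s2 = _mutate(s2, error_rate, rng)
                f1.write(f"@read{read_no}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@read{read_no}/2\n{s2}\n+\n{'I' * len(s2)}\n")
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return {"r1": r1_path, "r2": r2_path, "manifest": manifest_path}
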