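"""Synthetic proteome cohorts with known ground truth.

Generates benchmark cohorts that emulate the statistical structure of a
bacterial reference-proteome screen: each proteome is a bag of random decoy
proteins plus planted homologs of registry seed enzymes at controlled
sequence identity; proteomes belong to toy clades whose enzyme complements
mimic the broad phylogenetic patterns of energy-reserve pathways (e.g. the
trehalose route confined to an actinobacteria-like clade); and a configurable
proteome-size effect separates pathway-positive from pathway-negative groups
so that the size-contrast statistics can be exercised with known effect
sizes.

The generator makes no attempt at realistic sequence evolution: planted
homologs are full-length point-substituted copies of the seed (exact
identity contract), and decoys are i.i.d. residues from a stated background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, BACKGROUNDS, N_RESIDUES, random_protein
from .errors import ConfigurationError, InvalidParameterError
from .registry import SeedRegistry

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A small family of integer samplers for decoy counts and lengths.

    family: "normal" (rounded, params mean/sd), "poisson" (param lam) or
    "fixed" (param value).  Samples are clipped from below at ``minimum``.
    """

    family: str
    params: dict = field(default_factory=dict)
    minimum: int = 1

    def __post_init__(self) -> None:
        if self.family not in {"normal", "poisson", "fixed"}:
            raise InvalidParameterError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "normal":
            values = rng.normal(self.params["mean"], self.params["sd"], size)
            values = np.rint(values).astype(int)
        elif self.family == "poisson":
            values = rng.poisson(self.params["lam"], size).astype(int)
        else:
            values = np.full(size, int(self.params["value"]))
        return np.maximum(values, self.minimum)


@dataclass(frozen=True)
class Scenario:
    """One clade of the cohort: a label, the planted enzyme complement
    (enzyme id -> copy count) and the fraction of proteomes it receives."""

    clade: str
    complement: dict[str, int]
    fraction: float


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_proteomes: int = 100
    scenario_table: tuple[Scenario, ...] = ()
    homolog_identity_range: tuple[float, float] = (0.85, 0.95)
    decoy_count_sampler: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("normal", {"mean": 65, "sd": 5}, minimum=50)
    )
    decoy_length_sampler: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("normal", {"mean": 250, "sd": 60}, minimum=60)
    )
    #: Added to the decoy count of every pathway-positive proteome (one with a
    #: non-empty planted complement), leaving enzyme content and size
    #: independently controllable.
    size_effect: int = 0
    decoy_background: str = "uniform"
    genera_per_clade: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteomes < 2:
            raise InvalidParameterError("n_proteomes must be >= 2")
        if not self.scenario_table:
            raise InvalidParameterError("scenario_table must be non-empty")
        total = sum(s.fraction for s in self.scenario_table)
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"scenario fractions sum to {total}, expected 1")
        lo, hi = self.homolog_identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidParameterError(
                f"homolog identity range must satisfy 0 < low <= high <= 1, got {self.homolog_identity_range}"
            )
        if self.decoy_background not in BACKGROUNDS:
            raise InvalidParameterError(f"unknown background {self.decoy_background!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated proteome."""

    proteome_id: str
    lineage: tuple[str, ...]  # (domain, phylum/clade, genus)
    taxid: int
    planted_enzymes: dict[str, int]
    planted_identities: dict[str, list[float]]
    decoy_count: int

    @property
    def protein_count(self) -> int:
        return self.decoy_count + sum(self.planted_enzymes.values())


@dataclass
class Cohort:
    """A generated cohort: sequences, taxonomy and truth, all in memory."""

    config: CohortConfig
    proteomes: dict[str, list[tuple[str, str]]]  # proteome_id -> [(protein_id, seq)]
    truth: list[SyntheticTruth]

    def truth_by_id(self) -> dict[str, SyntheticTruth]:
        return {t.proteome_id: t for t in self.truth}

    def taxonomy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "proteome_id": t.proteome_id,
                    "taxid": t.taxid,
                    "domain": t.lineage[0],
                    "phylum": t.lineage[1],
                    "genus": t.lineage[2],
                }
                for t in self.truth
            ]
        )

    def truth_table(self, enzyme_ids: list[str] | None = None) -> pd.DataFrame:
        if enzyme_ids is None:
            enzyme_ids = sorted({e for t in self.truth for e in t.planted_enzymes})
        rows = []
        for t in self.truth:
            row = {
                "proteome_id": t.proteome_id,
                "clade": t.lineage[1],
                "decoy_count": t.decoy_count,
                "protein_count": t.protein_count,
            }
            for e in enzyme_ids:
                row[e] = t.planted_enzymes.get(e, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Write one FASTA per proteome plus taxonomy and truth tables."""
        from .io import write_fasta, write_tsv

        outdir = Path(outdir)
        (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
        for pid, records in self.proteomes.items():
            write_fasta(records, outdir / "proteomes" / f"{pid}.fasta")
        write_tsv(self.taxonomy_table(), outdir / "taxonomy.tsv")
        write_tsv(self.truth_table(), outdir / "truth.tsv")
        with (outdir / "truth.json").open("w") as fh:
            json.dump(
                [
                    {
                        "proteome_id": t.proteome_id,
                        "lineage": list(t.lineage),
                        "taxid": t.taxid,
                        "planted_enzymes": t.planted_enzymes,
                        "planted_identities": t.planted_identities,
                        "decoy_count": t.decoy_count,
                    }
                    for t in self.truth
                ],
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------


def mutate_homolog(seed_sequence: str, target_identity: float, rng: np.random.Generator) -> str:
    """Return a point-substituted copy of ``seed_sequence``.

    The returned sequence has the same length and Hamming identity to the
    seed of exactly ``round(target_identity * L) / L``.  Substituted
    positions are chosen uniformly without replacement and each substitution
    is uniform over the 19 alternative residues.
    """
    if not 0.0 < target_identity <= 1.0:
        raise InvalidParameterError(f"target_identity must be in (0, 1], got {target_identity}")
    if not seed_sequence:
        raise InvalidParameterError("seed_sequence is empty")
    length = len(seed_sequence)
    n_mut = length - int(round(target_identity * length))
    if n_mut == 0:
        return seed_sequence
    positions = rng.choice(length, size=n_mut, replace=False)
    residues = list(seed_sequence)
    for pos in positions:
        current = residues[pos]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        residues[pos] = alternatives[rng.integers(N_RESIDUES - 1)]
    return "".join(residues)


def generate_decoy(length: int, rng: np.random.Generator, background: np.ndarray | str = "uniform") -> str:
    """An i.i.d. decoy protein of ``length`` residues from ``background``."""
    if isinstance(background, str):
        background = BACKGROUNDS[background]
    return random_protein(length, rng, background=background)


def synthesize_homologs(
    name: str,
    seed_sequence: str,
    n: int,
    identity_range: tuple[float, float],
    rng: np.random.Generator,
    include_seed: bool = True,
) -> list[tuple[str, str]]:
    """A synthetic homolog set for model building: the seed itself plus ``n``
    point-substituted copies at identities uniform over ``identity_range``.

    Stands in for the homolog harvesting a real study performs against a
    sequence database.
    """
    lo, hi = identity_range
    records = [(f"{name}|seed", seed_sequence)] if include_seed else []
    for i in range(n):
        ident = rng.uniform(lo, hi)
        records.append((f"{name}|h{i + 1}", mutate_homolog(seed_sequence, ident, rng)))
    return records


def synthesize_homolog_store(
    registry: SeedRegistry,
    n_per_seed: int = 24,
    identity_range: tuple[float, float] = (0.80, 0.95),
    rng_seed: int = 0,
) -> tuple[dict[str, list], dict[str, list]]:
    """Homolog sets for every de novo enzyme and every Pfam domain.

    Returns ``(homolog_store, domain_homologs)`` suitable for
    :func:`reservescan.model_factory.build_model_library`.
    """
    from .registry import ModelPolicy

    rng = np.random.default_rng(rng_seed)
    homolog_store: dict[str, list] = {}
    for seed in registry:
        if seed.model_policy is ModelPolicy.DE_NOVO_FULL:
            homolog_store[seed.enzyme_id] = synthesize_homologs(
                seed.enzyme_id, seed.sequence, n_per_seed, identity_range, rng
            )
    domain_homologs: dict[str, list] = {}
    for pfam_id in sorted(registry.domain_sequences):
        domain_homologs[pfam_id] = synthesize_homologs(
            pfam_id, registry.domain_sequences[pfam_id], n_per_seed, identity_range, rng
        )
    return homolog_store, domain_homologs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _scenario_assignment(config: CohortConfig) -> list[Scenario]:
    """Deterministic largest-remainder allocation of proteomes to scenarios."""
    n = config.n_proteomes
    raw = [s.fraction * n for s in config.scenario_table]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    by_frac = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in by_frac[:remainder]:
        counts[i] += 1
    assignment = []
    for scenario, c in zip(config.scenario_table, counts):
        assignment.extend([scenario] * c)
    return assignment


def sample_truth(config: CohortConfig, registry: SeedRegistry) -> list[SyntheticTruth]:
    """Sample the cohort's ground-truth table without synthesising sequences.

    Used internally by :func:`generate_cohort` and directly by statistical
    power / type-I-error sweeps, where only proteome sizes and planted
    complements matter.
    """
    if len(registry) == 0:
        raise ConfigurationError("registry is empty")
    rng = np.random.default_rng(config.rng_seed)
    assignment = _scenario_assignment(config)
    decoys = config.decoy_count_sampler.sample(rng, config.n_proteomes)
    lo, hi = config.homolog_identity_range
    truths = []
    width = len(str(config.n_proteomes))
    clade_counter: dict[str, int] = {}
    for i, scenario in enumerate(assignment):
        pid = f"P{i + 1:0{width}d}"
        for enzyme_id in scenario.complement:
            registry[enzyme_id]  # raises KeyError for unknown enzymes
        planted: dict[str, int] = {e: c for e, c in scenario.complement.items() if c > 0}
        identities: dict[str, list[float]] = {}
        for enzyme_id, copies in planted.items():
            length = registry[enzyme_id].length_aa
            targets = rng.uniform(lo, hi, copies)
            identities[enzyme_id] = [round(t * length) / length for t in targets]
        decoy_count = int(decoys[i])
        if planted:
            decoy_count += config.size_effect
        j = clade_counter.get(scenario.clade, 0)
        clade_counter[scenario.clade] = j + 1
        genus = f"{scenario.clade}_g{j % config.genera_per_clade + 1}"
        truths.append(
            SyntheticTruth(
                proteome_id=pid,
                lineage=("Bacteria", scenario.clade, genus),
                taxid=100_000 + i,
                planted_enzymes=planted,
                planted_identities=identities,
                decoy_count=decoy_count,
            )
        )
    return truths


def generate_cohort(config: CohortConfig, registry: SeedRegistry) -> Cohort:
    """Generate a full cohort: sequences, taxonomy and truth.

    Planted homolog identities are realised exactly as recorded in the truth
    (within the rounding of one substitution); decoy counts of
    pathway-positive proteomes are shifted by ``config.size_effect``.  The
    whole cohort is a deterministic function of ``config.rng_seed``.
    """
    truths = sample_truth(config, registry)
    rng = np.random.default_rng((config.rng_seed, 1))
    background = BACKGROUNDS[config.decoy_background]
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for truth in truths:
        sequences: list[str] = []
        for enzyme_id in sorted(truth.planted_enzymes):
            seed_seq = registry[enzyme_id].sequence
            for ident in truth.planted_identities[enzyme_id]:
                sequences.append(mutate_homolog(seed_seq, ident, rng))
        lengths = config.decoy_length_sampler.sample(rng, truth.decoy_count)
        for length in lengths:
            sequences.append(generate_decoy(int(length), rng, background))
        order = rng.permutation(len(sequences))
        records = [
            (f"{truth.proteome_id}|p{i + 1}", sequences[j]) for i, j in enumerate(order)
        ]
        proteomes[truth.proteome_id] = records
    return Cohort(config=config, proteomes=proteomes, truth=truths)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Enzyme complements of the four toy clades.  They caricature the broad
#: patterns reported for real bacteria: a proteobacteria-like clade with the
#: classical glycogen route, full polyP metabolism, PhaABC (Group 2 synthase)
#: and WS/DGAT; an actinobacteria-like clade carrying the trehalose glycogen
#: route, Rv3032 and Group 1 synthase; a firmicutes-like clade with classical
#: glycogen (both branching-enzyme families) but no WS/DGAT; and a reduced,
#: mollicutes-like clade with no energy-reserve enzymes at all.
CLADE_COMPLEMENTS: dict[str, dict[str, int]] = {
    "Proteo_like": {
        "ppk1": 1, "ppk2": 1, "ppx": 1,
        "glgC": 1, "glgA": 1, "glgB_gh13": 1,
        "phaA": 1, "phaB": 1, "phaC_group2": 1,
        "ws_dgat": 1, "fabG": 1, "phaJ": 1, "pdat": 1,
    },
    "Actino_like": {
        "treS": 1, "pep2": 1, "glgE": 1, "glgB_gh13": 1,
        "rv3032": 1, "ppk1": 1, "ppk2": 1, "ppx": 1,
        "ws_dgat": 2, "phaC_group1": 1, "fabD": 1,
    },
    "Firmi_like": {
        "glgC": 1, "glgA": 1, "glgB_gh13": 1, "glgB_gh57": 1,
        "ppk1": 1, "ppx": 1,
        "phaA": 1, "phaB": 1, "phaC_group1": 1,
        "sucD": 1, "4hbD": 1, "orfZ": 1,
    },
    "Mollicute_like": {},
}

DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("Proteo_like", CLADE_COMPLEMENTS["Proteo_like"], 0.30),
    Scenario("Actino_like", CLADE_COMPLEMENTS["Actino_like"], 0.25),
    Scenario("Firmi_like", CLADE_COMPLEMENTS["Firmi_like"], 0.25),
    Scenario("Mollicute_like", CLADE_COMPLEMENTS["Mollicute_like"], 0.20),
)


def default_cohort_config(rng_seed: int = 0, **overrides) -> CohortConfig:
    """The package's reference benchmark conditions: 100 proteomes across the
    four toy clades, planted homologs at 0.85-0.95 identity, >= 50 decoys per
    proteome."""
    kwargs = dict(scenario_table=DEFAULT_SCENARIOS, rng_seed=rng_seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
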