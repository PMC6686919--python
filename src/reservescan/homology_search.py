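"""Profile-model screening of proteomes.

Each protein is scored against each enzyme model by best local Viterbi
alignment (log-odds in bits against the background null).  Scores are
converted to E-values through a Gumbel fit to the score distribution of
random background sequences, and hits are accepted under the screening rule:
E-value strictly below the threshold (default 1e-10) and aligned query span
strictly above the coverage fraction (default 60%) of the model's query
length.  Copy number of an enzyme in a proteome is the number of distinct
proteins accepted for that enzyme; enzymes modelled as several Pfam domains
require an accepted hit from every domain model on the same protein.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernels
from .alphabet import N_RESIDUES, encode, random_protein
from .errors import (
    CalibrationError,
    IntegrityError,
    InvalidParameterError,
    UncalibratedModelError,
)
from .model_factory import ProfileModel
from .registry import ModelPolicy, SeedRegistry

#: Raw hits with E-value above this cap are discarded before filtering; kept
#: hits therefore support re-filtering at any stricter threshold.
RAW_EVALUE_CAP = 10.0

#: Virtual enzyme id aggregating the two PhaC synthase groups: a protein
#: counts if it is accepted for either group model.
PHAC_ANY = "phaC_any"
_PHAC_GROUPS = ("phaC_group1", "phaC_group2")


class DatabaseSizePolicy(enum.Enum):
    """What N multiplies the Gumbel tail probability in E = N * P(S > s)."""

    PER_PROTEOME = "per_proteome"  # N = protein count of the searched proteome
    FIXED_N = "fixed_n"


@dataclass(frozen=True)
class ScreeningConfig:
    """Hit-acceptance thresholds and E-value scaling policy."""

    evalue_max: float = 1e-10  # accept strictly below
    min_query_coverage: float = 0.60  # accept strictly above
    database_size_policy: DatabaseSizePolicy = DatabaseSizePolicy.PER_PROTEOME
    fixed_n: int | None = None

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise InvalidParameterError("evalue_max must be positive")
        if not 0.0 < self.min_query_coverage <= 1.0:
            raise InvalidParameterError("min_query_coverage must be in (0, 1]")
        if self.database_size_policy is DatabaseSizePolicy.FIXED_N and not self.fixed_n:
            raise InvalidParameterError("FIXED_N policy requires fixed_n")


@dataclass(frozen=True)
class Hit:
    """One accepted-or-candidate alignment of a protein against a model.

    Spans are 0-based half-open: ``query_span`` over model match states,
    ``target_span`` over protein coordinates.  ``query_coverage`` is the
    query-span length divided by the model's query length.
    """

    enzyme_id: str
    model_id: str
    proteome_id: str
    protein_id: str
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    query_coverage: float


@dataclass(frozen=True)
class EnzymeProfile:
    """Per-proteome enzyme copy counts."""

    proteome_id: str
    copy_counts: dict[str, int]
    proteome_size: int


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class ModelScorer:
    """Precomputed log-odds tables for scoring many proteins against one model."""

    def __init__(self, model: ProfileModel):
        self.model = model
        m = model.match_length
        with np.errstate(divide="ignore"):
            lm = np.log2(model.match_emissions / model.background)
            self._ins = np.append(np.log2(model.insert_emissions / model.background), 0.0)
            self._lMM = np.log2(model.t_match[:, 0])
            self._lMI = np.log2(model.t_match[:, 1])
            self._lMD = np.log2(model.t_match[:, 2])
            self._lIM = np.log2(model.t_insert[:, 0])
            self._lII = np.log2(model.t_insert[:, 1])
            self._lDM = np.log2(model.t_delete[:, 0])
            self._lDD = np.log2(model.t_delete[:, 1])
        for arr in (self._lMM, self._lMI, self._lMD, self._lIM, self._lII, self._lDM, self._lDD):
            np.nan_to_num(arr, copy=False, neginf=_kernels.NEG_INF)
        # column for ambiguous residues scores 0 (emitted by background)
        self._lm_ext = np.hstack([lm, np.zeros((m, 1))])
        self._entry = -math.log2(m)

    def score_encoded(self, seq: np.ndarray) -> tuple[float, tuple[int, int], tuple[int, int]]:
        em = np.ascontiguousarray(self._lm_ext[:, seq].T)
        ins = self._ins[seq].astype(np.float64)
        score, t0, t1, k0, k1 = _kernels.viterbi_local(
            em, ins, self._lMM, self._lMI, self._lMD,
            self._lIM, self._lII, self._lDM, self._lDD, self._entry,
        )
        return float(score), (int(k0), int(k1) + 1), (int(t0), int(t1) + 1)


def score_sequence(model: ProfileModel, protein: str) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Best local log-odds score (bits) of ``protein`` against ``model``.

    Returns ``(bit_score, query_span, target_span)`` where the spans are the
    maximising alignment's extents (0-based half-open).
    """
    if not protein:
        raise InvalidParameterError("protein sequence is empty")
    return ModelScorer(model).score_encoded(encode(protein))


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------


def _gumbel_mle(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (beta=scale, mu=location).

    The scale solves the standard profile-likelihood equation by bracketed
    root finding; the estimator is exactly equivariant under shifts and
    scalings of the sample.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise CalibrationError("score distribution has zero variance")
    xbar = x.mean()

    def h(beta: float) -> float:
        z = -x / beta
        z -= z.max()
        w = np.exp(z)
        return beta - xbar + float((x * w).sum() / w.sum())

    lo, hi = sd / 100.0, sd * 100.0
    # h is increasing in beta; expand the bracket if necessary
    for _ in range(60):
        if h(lo) < 0:
            break
        lo /= 2.0
    for _ in range(60):
        if h(hi) > 0:
            break
        hi *= 2.0
    beta = float(brentq(h, lo, hi, xtol=1e-12 * sd, rtol=1e-14))
    z = -x / beta
    zmax = z.max()
    mu = -beta * (math.log(np.exp(z - zmax).mean()) + zmax)
    return beta, float(mu)


def calibrate(
    model: ProfileModel, n_random: int = 200, rng: np.random.Generator | int = 0
) -> tuple[float, float]:
    """Fit the Gumbel E-value parameters of a model.

    Scores ``n_random`` background-sampled sequences of the model's consensus
    length and fits a Gumbel by maximum likelihood.  Stores and returns
    ``(lambda, mu)`` with ``lambda = 1 / scale``.
    """
    if n_random < 100:
        raise InvalidParameterError("n_random must be >= 100 for a stable fit")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    scorer = ModelScorer(model)
    length = model.match_length
    scores = np.empty(n_random)
    for i in range(n_random):
        seq = encode(random_protein(length, rng, background=model.background))
        scores[i] = scorer.score_encoded(seq)[0]
    beta, mu = _gumbel_mle(scores)
    model.calibration = (1.0 / beta, mu)
    return model.calibration


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Fit (lambda, mu) to an arbitrary score sample (exposed for testing
    shift/scale behaviour of the calibration)."""
    beta, mu = _gumbel_mle(np.asarray(scores, dtype=float))
    return 1.0 / beta, mu


def evalue_of(score: float, model: ProfileModel, n_targets: int) -> float:
    """Convert a bit score to an E-value: ``min(n, n * exp(-lambda*(s-mu)))``.

    Monotonically decreasing in score and linear in ``n_targets``.
    """
    if model.calibration is None:
        raise UncalibratedModelError(f"model {model.model_id!r} is not calibrated")
    lam, mu = model.calibration
    e = n_targets * math.exp(-lam * (score - mu))
    return min(float(e), float(n_targets))


def calibrate_library(
    models_by_enzyme: dict[str, list[ProfileModel]],
    n_random: int = 200,
    rng_seed: int = 0,
) -> None:
    """Calibrate every model in a library, deterministically from one seed."""
    import zlib

    for enzyme_id in sorted(models_by_enzyme):
        for j, model in enumerate(models_by_enzyme[enzyme_id]):
            key = zlib.crc32(enzyme_id.encode()) % (2**31)
            sub = np.random.default_rng((rng_seed, key, j))
            calibrate(model, n_random=n_random, rng=sub)


# ---------------------------------------------------------------------------
# filtering and counting
# ---------------------------------------------------------------------------


def filter_hits(hits: list[Hit], config: ScreeningConfig) -> list[Hit]:
    """Keep exactly the hits with ``evalue < evalue_max`` and
    ``query_coverage > min_query_coverage`` (both strict); order preserved."""
    return [
        h
        for h in hits
        if h.evalue < config.evalue_max and h.query_coverage > config.min_query_coverage
    ]


def _expected_model_ids(seed) -> list[str]:
    if seed.model_policy is ModelPolicy.DE_NOVO_FULL:
        return [f"{seed.enzyme_id}:denovo"]
    return [f"{seed.enzyme_id}:{d}" for d in seed.pfam_domain_ids]


def count_copies(
    kept_hits: list[Hit],
    registry: SeedRegistry,
    proteome: tuple[str, list[tuple[str, str]]],
) -> EnzymeProfile:
    """Collapse accepted hits into per-enzyme copy counts for one proteome.

    A protein contributes at most one copy per enzyme regardless of how many
    hits it received; enzymes under the per-domain policy require accepted
    hits from **all** of their domain models on the same protein.  When both
    PhaC group enzymes are in the registry, a derived ``phaC_any`` count
    (either group) is added for pathway calling.
    """
    proteome_id, records = proteome
    known_proteins = {rec_id for rec_id, _ in records}
    by_model: dict[str, set[str]] = {}
    for h in kept_hits:
        if h.proteome_id != proteome_id:
            continue
        if h.protein_id not in known_proteins:
            raise IntegrityError(
                f"hit references unknown protein {h.protein_id!r} in {proteome_id}"
            )
        by_model.setdefault(h.model_id, set()).add(h.protein_id)
    counts: dict[str, int] = {}
    accepted_proteins: dict[str, set[str]] = {}
    for seed in registry:
        model_ids = _expected_model_ids(seed)
        sets = [by_model.get(mid, set()) for mid in model_ids]
        proteins = set.intersection(*sets) if sets else set()
        accepted_proteins[seed.enzyme_id] = proteins
        counts[seed.enzyme_id] = len(proteins)
    if all(g in counts for g in _PHAC_GROUPS):
        counts[PHAC_ANY] = len(accepted_proteins[_PHAC_GROUPS[0]] | accepted_proteins[_PHAC_GROUPS[1]])
    return EnzymeProfile(proteome_id=proteome_id, copy_counts=counts, proteome_size=len(records))


# ---------------------------------------------------------------------------
# cohort screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Raw hits plus filtered per-proteome enzyme profiles."""

    profiles: list[EnzymeProfile]
    raw_hits: list[Hit]
    kept_hits: list[Hit]
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "enzyme_id": h.enzyme_id,
                    "model_id": h.model_id,
                    "proteome_id": h.proteome_id,
                    "protein_id": h.protein_id,
                    "bit_score": h.bit_score,
                    "evalue": h.evalue,
                    "query_start": h.query_span[0],
                    "query_end": h.query_span[1],
                    "target_start": h.target_span[0],
                    "target_end": h.target_span[1],
                    "query_coverage": h.query_coverage,
                }
                for h in self.kept_hits
            ]
        )

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {"proteome_id": p.proteome_id, "proteome_size": p.proteome_size}
            row.update(p.copy_counts)
            rows.append(row)
        return pd.DataFrame(rows)


def screen_proteome(
    models_by_enzyme: dict[str, list[ProfileModel]],
    proteome_id: str,
    records: list[tuple[str, str]],
    config: ScreeningConfig,
) -> list[Hit]:
    """Score one proteome against every model; returns raw candidate hits
    (E-value <= RAW_EVALUE_CAP), unfiltered."""
    if config.database_size_policy is DatabaseSizePolicy.PER_PROTEOME:
        n_targets = len(records)
    else:
        n_targets = int(config.fixed_n)
    encoded = [(rec_id, encode(seq)) for rec_id, seq in records]
    hits: list[Hit] = []
    for enzyme_id in sorted(models_by_enzyme):
        for model in models_by_enzyme[enzyme_id]:
            scorer = ModelScorer(model)
            qlen = model.query_length_aa
            for rec_id, seq in encoded:
                score, qspan, tspan = scorer.score_encoded(seq)
                e = evalue_of(score, model, n_targets)
                if e > RAW_EVALUE_CAP:
                    continue
                hits.append(
                    Hit(
                        enzyme_id=enzyme_id,
                        model_id=model.model_id,
                        proteome_id=proteome_id,
                        protein_id=rec_id,
                        bit_score=score,
                        evalue=e,
                        query_span=qspan,
                        target_span=tspan,
                        query_coverage=(qspan[1] - qspan[0]) / qlen,
                    )
                )
    return hits


def screen_cohort(
    models_by_enzyme: dict[str, list[ProfileModel]],
    proteomes: dict[str, list[tuple[str, str]]],
    config: ScreeningConfig,
    registry: SeedRegistry,
) -> ScreenResult:
    """Screen every proteome of a cohort; deterministic given models/config."""
    raw: list[Hit] = []
    profiles: list[EnzymeProfile] = []
    for proteome_id in proteomes:
        records = proteomes[proteome_id]
        proteome_hits = screen_proteome(models_by_enzyme, proteome_id, records, config)
        raw.extend(proteome_hits)
        kept = filter_hits(proteome_hits, config)
        profiles.append(count_copies(kept, registry, (proteome_id, records)))
    return ScreenResult(
        profiles=profiles, raw_hits=raw, kept_hits=filter_hits(raw, config), config=config
    )


def recount_at(
    result: ScreenResult,
    config: ScreeningConfig,
    registry: SeedRegistry,
    proteomes: dict[str, list[tuple[str, str]]],
) -> list[EnzymeProfile]:
    """Re-filter the raw hits of an existing screen at different thresholds
    and recompute copy counts (used for threshold sensitivity sweeps)."""
    by_proteome: dict[str, list[Hit]] = {pid: [] for pid in proteomes}
    for h in filter_hits(result.raw_hits, config):
        by_proteome[h.proteome_id].append(h)
    return [
        count_copies(by_proteome[pid], registry, (pid, proteomes[pid]))
        for pid in proteomes
    ]


# ---------------------------------------------------------------------------
# optional HMMER3 --domtblout reader
# ---------------------------------------------------------------------------


def read_domtblout(source, proteome_id: str = "") -> list[Hit]:
    """Map a HMMER3 ``--domtblout`` table onto :class:`Hit` records.

    The query name is taken as the model id (an ``enzyme:domain`` prefix, if
    present, supplies the enzyme id); coverage is the aligned HMM span over
    the query length.  Lets an external search engine stand in for the
    embedded scorer, with everything downstream unchanged.
    """
    from pathlib import Path

    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    hits = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        model_id = f[3]
        qlen = int(f[5])
        hmm_from, hmm_to = int(f[15]), int(f[16])
        ali_from, ali_to = int(f[17]), int(f[18])
        enzyme_id = model_id.split(":", 1)[0]
        hits.append(
            Hit(
                enzyme_id=enzyme_id,
                model_id=model_id,
                proteome_id=proteome_id,
                protein_id=f[0],
                bit_score=float(f[13]),
                evalue=float(f[12]),
                query_span=(hmm_from - 1, hmm_to),
                target_span=(ali_from - 1, ali_to),
                query_coverage=(hmm_to - hmm_from + 1) / qlen,
            )
        )
    return hits
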