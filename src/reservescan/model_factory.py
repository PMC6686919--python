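"""Construction of profile models for seed enzymes.

The model-building route mirrors standard practice for protein-family
profiles: a homolog set is dereplicated at 98% identity, aligned
progressively, the ragged alignment termini are trimmed by a column-occupancy
rule, and a position-specific match/insert/delete profile is estimated with
background-weighted pseudocounts.  Depending on the per-enzyme policy, either
one full-length model is built de novo from the enzyme's homolog set, or one
model per annotated Pfam domain is drawn from a domain-model store.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .alphabet import (
    AMINO_ACIDS,
    N_RESIDUES,
    UNIFORM_BACKGROUND,
    encode,
    encode_aligned,
)
from .errors import (
    ConfigurationError,
    DegenerateAlignmentError,
    InvalidParameterError,
)
from .registry import ModelPolicy, SeedEnzyme

GAP = "-"

#: Linear gap penalty used by the progressive aligner (match scores are
#: column identity fractions in [0, 1], so a gap costs a bit more than half
#: a perfect match).
MSA_GAP_PENALTY = -0.6

# Transition pseudocount priors (successor order as stored):
# match -> (M, I, D); insert -> (M, I); delete -> (M, D).
PRIOR_MATCH = np.array([0.90, 0.05, 0.05])
PRIOR_INSERT = np.array([0.80, 0.20])
PRIOR_DELETE = np.array([0.70, 0.30])

PROFILE_FORMAT_VERSION = "reservescan-profile-1"


# ---------------------------------------------------------------------------
# pairwise identity and dereplication
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two proteins under global alignment.

    The alignment maximises the number of identically matched columns and,
    among such alignments, minimises the number of gap columns; identity is
    matched columns divided by total alignment columns.  The value is
    symmetric, lies in [0, 1], and equals 1 exactly for identical sequences.
    """
    if not a or not b:
        raise InvalidParameterError("pairwise_identity requires non-empty sequences")
    ea, eb = encode(a), encode(b)
    K = len(a) + len(b) + 1
    f = int(_kernels.identity_dp(ea, eb, np.int64(K)))
    if f % K == 0:
        matches, gaps = f // K, 0
    else:
        matches = f // K + 1
        gaps = K - f % K
    columns = (len(a) + len(b) + gaps) / 2.0
    return matches / columns


def dereplicate(sequences: list, threshold: float = 0.98) -> list:
    """Greedy dereplication: drop any sequence more than ``threshold``
    identical to an already-kept representative.

    Sequences are processed in input order; a sequence is kept iff its
    identity to every previously kept representative is <= threshold.  The
    operation preserves input order and is idempotent.  Accepts plain strings
    or ``(id, sequence)`` pairs.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError(f"threshold must be in (0, 1], got {threshold}")
    if not sequences:
        raise InvalidParameterError("dereplicate requires a non-empty list")
    kept: list = []
    for item in sequences:
        seq = item[1] if isinstance(item, tuple) else item
        redundant = False
        for rep in kept:
            rep_seq = rep[1] if isinstance(rep, tuple) else rep
            if pairwise_identity(seq, rep_seq) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(item)
    return kept


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InvalidParameterError("alignment has no rows")
        n = len(self.rows[0][1])
        if any(len(aligned) != n for _, aligned in self.rows):
            raise InvalidParameterError("alignment rows differ in length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def row_count(self) -> int:
        return len(self.rows)

    def degapped(self, index: int) -> str:
        return self.rows[index][1].replace(GAP, "")

    def occupancy(self) -> np.ndarray:
        """Fraction of non-gap residues per column."""
        mat = np.array([list(r) for _, r in self.rows])
        return (mat != GAP).mean(axis=0)

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(self.rows, path)

    def to_stockholm(self, path) -> None:
        path = Path(path)
        width = max(len(i) for i, _ in self.rows) + 2
        with path.open("w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for rec_id, aligned in self.rows:
                fh.write(f"{rec_id:<{width}}{aligned}\n")
            fh.write("//\n")

    @classmethod
    def from_fasta(cls, source) -> "Msa":
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        if isinstance(source, (str, Path)):
            lines = Path(source).read_text().splitlines()
        else:
            lines = list(source)
        rows = [
            (header.split()[0], seq.upper())
            for header, seq in SimpleFastaParser(iter(line + "\n" for line in lines))
        ]
        return cls(rows=tuple(rows))

    @classmethod
    def from_stockholm(cls, source) -> "Msa":
        if isinstance(source, (str, Path)):
            lines = Path(source).read_text().splitlines()
        else:
            lines = list(source)
        rows = []
        for line in lines:
            line = line.rstrip()
            if not line or line.startswith("#") or line.startswith("//"):
                continue
            rec_id, aligned = line.split(None, 1)
            rows.append((rec_id, aligned.replace(".", GAP).upper()))
        return cls(rows=tuple(rows))


def _normalize_inputs(sequences: list) -> list[tuple[str, str]]:
    out = []
    for i, item in enumerate(sequences):
        if isinstance(item, tuple):
            out.append((item[0], item[1]))
        else:
            out.append((f"seq{i + 1}", item))
    return out


def build_msa(sequences: list) -> Msa:
    """Progressive multiple alignment.

    Sequences are added in a guide order derived from pairwise identity (the
    closest pair first, then the sequence closest on average to the growing
    alignment).  Each addition aligns the sequence against the current
    alignment columns with a linear gap penalty; columns are scored by the
    fraction of residues matching the incoming residue.  Deleting gaps from
    any output row recovers the corresponding input sequence.
    """
    records = _normalize_inputs(sequences)
    if len(records) < 2:
        raise InvalidParameterError("build_msa requires at least 2 sequences")
    n = len(records)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(records[i][1], records[j][1])
    # guide order: closest pair, then nearest-by-average-identity additions
    iu = np.triu_indices(n, 1)
    if n == 2:
        order = [0, 1]
    else:
        flat = np.argmax(ident[iu])
        first, second = iu[0][flat], iu[1][flat]
        order = [int(first), int(second)]
        remaining = [k for k in range(n) if k not in order]
        while remaining:
            avg = [(ident[k, order].mean(), -k) for k in remaining]
            best = max(range(len(remaining)), key=lambda idx: avg[idx])
            order.append(remaining.pop(best))

    # alignment as int16 matrix, -1 = gap
    first_seq = encode(records[order[0]][1]).astype(np.int16)
    aln = first_seq.reshape(1, -1)
    row_ids = [order[0]]
    for k in order[1:]:
        seq = encode(records[k][1]).astype(np.int16)
        n_rows, n_cols = aln.shape
        counts = np.zeros((n_cols, N_RESIDUES + 1), dtype=np.float64)
        for r in range(n_rows):
            valid = aln[r] >= 0
            counts[np.nonzero(valid)[0], aln[r][valid]] += 1.0
        S = counts[:, np.minimum(seq, N_RESIDUES)].T / n_rows  # (len(seq), n_cols)
        ops = _kernels.nw_path(np.ascontiguousarray(S), MSA_GAP_PENALTY)
        new_cols = len(ops)
        new_aln = np.full((n_rows + 1, new_cols), -1, dtype=np.int16)
        ci = 0  # index into seq
        cj = 0  # index into old columns
        for c, op in enumerate(ops):
            if op == 0:
                new_aln[:n_rows, c] = aln[:, cj]
                new_aln[n_rows, c] = seq[ci]
                ci += 1
                cj += 1
            elif op == 1:  # residue of the new sequence, gap column in profile
                new_aln[n_rows, c] = seq[ci]
                ci += 1
            else:  # op == 2: existing column, gap in new sequence
                new_aln[:n_rows, c] = aln[:, cj]
                cj += 1
        aln = new_aln
        row_ids.append(k)

    def render(row: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[v] if 0 <= v < N_RESIDUES else ("X" if v == N_RESIDUES else GAP) for v in row)

    # restore input order
    by_input = sorted(range(len(row_ids)), key=lambda r: row_ids[r])
    rows = tuple((records[row_ids[r]][0], render(aln[r])) for r in by_input)
    return Msa(rows=rows)


def trim_termini(msa: Msa, min_occupancy: float = 0.5) -> Msa:
    """Remove leading and trailing columns whose non-gap occupancy is below
    ``min_occupancy``; interior columns are never touched.

    This automates the usual manual clean-up of ragged alignment termini
    with a deterministic rule.
    """
    if not 0.0 <= min_occupancy <= 1.0:
        raise InvalidParameterError(f"min_occupancy must be in [0, 1], got {min_occupancy}")
    occ = msa.occupancy()
    lo = 0
    hi = msa.column_count
    while lo < hi and occ[lo] < min_occupancy:
        lo += 1
    while hi > lo and occ[hi - 1] < min_occupancy:
        hi -= 1
    if lo >= hi:
        raise DegenerateAlignmentError(
            f"trimming at occupancy {min_occupancy} removes every column"
        )
    if lo == 0 and hi == msa.column_count:
        return msa
    return Msa(rows=tuple((i, s[lo:hi]) for i, s in msa.rows))


# ---------------------------------------------------------------------------
# profile model
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Position-specific match/insert/delete profile with E-value calibration.

    Emission and transition matrices are probability distributions (rows sum
    to 1).  ``calibration`` holds the Gumbel parameters ``(lambda, mu)`` used
    for score-to-E-value conversion, or ``None`` before calibration.
    ``query_length_aa`` is the denominator of the query-coverage rule applied
    to hits against this model.
    """

    model_id: str
    source_enzyme: str
    match_emissions: np.ndarray  # (m, 20)
    insert_emissions: np.ndarray  # (20,)
    t_match: np.ndarray  # (m, 3): M->M, M->I, M->D
    t_insert: np.ndarray  # (m, 2): I->M, I->I
    t_delete: np.ndarray  # (m, 2): D->M, D->D
    background: np.ndarray  # (20,)
    query_length_aa: int
    calibration: tuple[float, float] | None = None
    consensus: str = field(default="")

    @property
    def match_length(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        self.validate()
        if not self.consensus:
            idx = np.argmax(self.match_emissions, axis=1)
            self.consensus = "".join(AMINO_ACIDS[i] for i in idx)

    def validate(self) -> None:
        m = self.match_emissions.shape[0]
        if m < 1:
            raise DegenerateAlignmentError("model must have at least one match state")
        if self.query_length_aa < 1:
            raise InvalidParameterError("query_length_aa must be positive")
        for name, arr, width in (
            ("match_emissions", self.match_emissions, N_RESIDUES),
            ("t_match", self.t_match, 3),
            ("t_insert", self.t_insert, 2),
            ("t_delete", self.t_delete, 2),
        ):
            if arr.shape != (m, width):
                raise InvalidParameterError(f"{name} has shape {arr.shape}, expected {(m, width)}")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidParameterError(f"{name} rows do not sum to 1")
            if (arr < 0).any():
                raise InvalidParameterError(f"{name} has negative probabilities")
        for name, vec in (("insert_emissions", self.insert_emissions), ("background", self.background)):
            if vec.shape != (N_RESIDUES,):
                raise InvalidParameterError(f"{name} has shape {vec.shape}")
            if not np.isclose(vec.sum(), 1.0, atol=1e-9):
                raise InvalidParameterError(f"{name} does not sum to 1")

    def with_calibration(self, lam: float, mu: float) -> "ProfileModel":
        return replace(self, calibration=(float(lam), float(mu)))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": PROFILE_FORMAT_VERSION,
            "model_id": self.model_id,
            "source_enzyme": self.source_enzyme,
            "query_length_aa": int(self.query_length_aa),
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "t_match": self.t_match.tolist(),
            "t_insert": self.t_insert.tolist(),
            "t_delete": self.t_delete.tolist(),
            "background": self.background.tolist(),
            "calibration": list(self.calibration) if self.calibration else None,
            "consensus": self.consensus,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileModel":
        if d.get("format") != PROFILE_FORMAT_VERSION:
            raise ConfigurationError(f"unsupported profile format {d.get('format')!r}")
        return cls(
            model_id=d["model_id"],
            source_enzyme=d["source_enzyme"],
            match_emissions=np.array(d["match_emissions"], dtype=float),
            insert_emissions=np.array(d["insert_emissions"], dtype=float),
            t_match=np.array(d["t_match"], dtype=float),
            t_insert=np.array(d["t_insert"], dtype=float),
            t_delete=np.array(d["t_delete"], dtype=float),
            background=np.array(d["background"], dtype=float),
            query_length_aa=int(d["query_length_aa"]),
            calibration=tuple(d["calibration"]) if d.get("calibration") else None,
            consensus=d.get("consensus", ""),
        )


def build_profile(
    msa: Msa,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    model_id: str = "model",
    source_enzyme: str = "",
) -> ProfileModel:
    """Estimate a profile model from a (trimmed) alignment.

    Match states are the columns with non-gap occupancy >= 0.5.  Match
    emissions are ``(count + w * q) / (n_residues + w)`` with background ``q``
    and pseudocount weight ``w``; transition probabilities are estimated the
    same way against fixed prior transition distributions.  Insert states
    emit the background.  ``query_length_aa`` is set to the match length.
    """
    if pseudocount_weight <= 0:
        raise InvalidParameterError("pseudocount_weight must be positive")
    if msa.row_count < 2:
        raise InvalidParameterError("build_profile requires an alignment with >= 2 rows")
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    q = q / q.sum()
    w = float(pseudocount_weight)

    mat = np.stack([encode_aligned(aligned) for _, aligned in msa.rows])
    occ = (mat >= 0).mean(axis=0)
    match_cols = np.nonzero(occ >= 0.5)[0]
    if match_cols.size == 0:
        raise DegenerateAlignmentError("no column reaches 0.5 occupancy")
    m = match_cols.size

    # emissions
    emissions = np.empty((m, N_RESIDUES))
    for s, col in enumerate(match_cols):
        residues = mat[:, col]
        standard = residues[(residues >= 0) & (residues < N_RESIDUES)]
        counts = np.bincount(standard, minlength=N_RESIDUES).astype(float)
        n_res = float(standard.size)
        emissions[s] = (counts + w * q) / (n_res + w)

    # transitions between consecutive match states
    cM = np.zeros((m, 3))
    cI = np.zeros((m, 2))
    cD = np.zeros((m, 2))
    for r in range(msa.row_count):
        row = mat[r]
        for s in range(m - 1):
            c0, c1 = match_cols[s], match_cols[s + 1]
            here = row[c0] >= 0
            there = row[c1] >= 0
            between = row[c0 + 1 : c1]
            n_ins = int((between >= 0).sum()) if here else 0
            if here:
                if n_ins == 0:
                    cM[s, 0 if there else 2] += 1
                else:
                    cM[s, 1] += 1
                    cI[s, 1] += n_ins - 1
                    if there:
                        cI[s, 0] += 1
                    else:
                        cI[s, 1] += 1  # I->D is not modelled; folded into I->I
            else:
                cD[s, 0 if there else 1] += 1
    t_match = (cM + w * PRIOR_MATCH) / (cM.sum(axis=1, keepdims=True) + w)
    t_insert = (cI + w * PRIOR_INSERT) / (cI.sum(axis=1, keepdims=True) + w)
    t_delete = (cD + w * PRIOR_DELETE) / (cD.sum(axis=1, keepdims=True) + w)
    # terminal state: exit only
    t_match[m - 1] = [1.0, 0.0, 0.0]
    t_insert[m - 1] = [1.0, 0.0]
    t_delete[m - 1] = [1.0, 0.0]

    return ProfileModel(
        model_id=model_id,
        source_enzyme=source_enzyme,
        match_emissions=emissions,
        insert_emissions=q.copy(),
        t_match=t_match,
        t_insert=t_insert,
        t_delete=t_delete,
        background=q.copy(),
        query_length_aa=m,
    )


# ---------------------------------------------------------------------------
# policy resolution and library building
# ---------------------------------------------------------------------------

def _build_from_homologs(
    name: str,
    homologs: list,
    pseudocount_weight: float,
    background: np.ndarray | None,
    source_enzyme: str,
    derep_threshold: float = 0.98,
    min_occupancy: float = 0.5,
) -> ProfileModel:
    reps = dereplicate(homologs, threshold=derep_threshold)
    if len(reps) < 2:
        raise ConfigurationError(
            f"homolog set for {name!r} has fewer than 2 representatives after dereplication"
        )
    msa = trim_termini(build_msa(reps), min_occupancy=min_occupancy)
    return build_profile(
        msa,
        pseudocount_weight=pseudocount_weight,
        background=background,
        model_id=name,
        source_enzyme=source_enzyme,
    )


def resolve_models(
    seed: SeedEnzyme,
    homolog_store: dict[str, list],
    domain_model_store: dict[str, ProfileModel],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> list[ProfileModel]:
    """Materialise the model(s) screening will use for one seed enzyme.

    DE_NOVO_FULL enzymes get a single full-sequence model built from their
    homolog set; PFAM_DOMAINS enzymes get one pre-built model per listed Pfam
    domain from ``domain_model_store``.
    """
    if seed.model_policy is ModelPolicy.DE_NOVO_FULL:
        homologs = homolog_store.get(seed.enzyme_id)
        if not homologs:
            raise ConfigurationError(f"no homolog set for de novo enzyme {seed.enzyme_id!r}")
        model = _build_from_homologs(
            f"{seed.enzyme_id}:denovo",
            homologs,
            pseudocount_weight,
            background,
            source_enzyme=seed.enzyme_id,
        )
        return [model]
    models = []
    for pfam_id in seed.pfam_domain_ids:
        model = domain_model_store.get(pfam_id)
        if model is None:
            raise ConfigurationError(
                f"domain model {pfam_id!r} required by enzyme {seed.enzyme_id!r} is missing"
            )
        models.append(replace(model, source_enzyme=seed.enzyme_id, model_id=f"{seed.enzyme_id}:{pfam_id}"))
    return models


def build_domain_model_store(
    domain_homologs: dict[str, list],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> dict[str, ProfileModel]:
    """Build one profile per Pfam domain id from its homolog set."""
    store = {}
    for pfam_id in sorted(domain_homologs):
        store[pfam_id] = _build_from_homologs(
            pfam_id, domain_homologs[pfam_id], pseudocount_weight, background, source_enzyme=""
        )
    return store


def build_model_library(
    registry,
    homolog_store: dict[str, list],
    domain_homologs: dict[str, list],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> dict[str, list[ProfileModel]]:
    """Resolve models for every enzyme in the registry.

    Returns ``{enzyme_id: [ProfileModel, ...]}`` — one model for de novo
    enzymes, one per Pfam domain otherwise.
    """
    domain_store = build_domain_model_store(
        domain_homologs, pseudocount_weight=pseudocount_weight, background=background
    )
    return {
        seed.enzyme_id: resolve_models(
            seed, homolog_store, domain_store,
            pseudocount_weight=pseudocount_weight, background=background,
        )
        for seed in registry
    }


# ---------------------------------------------------------------------------
# optional HMMER3 ASCII importer (match emissions and length only)
# ---------------------------------------------------------------------------

def read_hmmer3_profile(source, model_id: str | None = None) -> ProfileModel:
    """Import match emissions from a HMMER3 ASCII ``.hmm`` file.

    Only the match-emission table and model length are read; transitions are
    replaced by the package's default priors and the model needs calibration
    before E-values can be computed.  Useful for plugging in externally built
    profiles.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    name = model_id or "hmmer3_import"
    length = None
    hmm_alphabet: list[str] = []
    emissions: list[list[float]] = []
    in_model = False
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "NAME" and model_id is None:
            name = parts[1]
        elif parts[0] == "LENG":
            length = int(parts[1])
        elif parts[0] == "HMM":
            hmm_alphabet = parts[1:]
            in_model = True
        elif in_model and parts[0].isdigit():
            scores = [float(x) if x != "*" else np.inf for x in parts[1 : 1 + len(hmm_alphabet)]]
            probs = np.exp(-np.array(scores))
            emissions.append(probs.tolist())
    if length is None or not emissions:
        raise ConfigurationError("not a parsable HMMER3 ASCII profile")
    em = np.array(emissions)
    # reorder the HMMER alphabet columns into our alphabetical order
    order = [hmm_alphabet.index(a) for a in AMINO_ACIDS]
    em = em[:, order]
    em = em / em.sum(axis=1, keepdims=True)
    m = em.shape[0]
    t_match = np.tile(PRIOR_MATCH, (m, 1))
    t_insert = np.tile(PRIOR_INSERT, (m, 1))
    t_delete = np.tile(PRIOR_DELETE, (m, 1))
    t_match[m - 1] = [1.0, 0.0, 0.0]
    t_insert[m - 1] = [1.0, 0.0]
    t_delete[m - 1] = [1.0, 0.0]
    return ProfileModel(
        model_id=name,
        source_enzyme="",
        match_emissions=em,
        insert_emissions=UNIFORM_BACKGROUND.copy(),
        t_match=t_match,
        t_insert=t_insert,
        t_delete=t_delete,
        background=UNIFORM_BACKGROUND.copy(),
        query_length_aa=m,
    )
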