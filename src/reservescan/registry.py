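"""Seed-enzyme registry for the five bacterial energy reserves.

The registry holds one record per key enzyme of polyphosphate, glycogen,
wax-ester, triacylglycerol and polyhydroxyalkanoate metabolism: the reference
species, gene, UniProt accession, sequence length, Pfam domain composition and
the model-construction policy (full-length de novo profile vs. one profile per
Pfam domain).

The amino-acid sequences shipped with the package are SYNTHETIC stand-ins for
the UniProt reference sequences: they reproduce the published lengths and
domain layouts (including domains shared between enzymes) but their residue
content is randomly generated, so that the whole pipeline can be exercised and
benchmarked without any external database.  Enzymes under the per-domain
policy carry explicit domain coordinates; a shared Pfam domain (e.g. PF00534
in both glycogen synthases) embeds the *same* synthetic domain sequence in
every seed that lists it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

from .io import read_fasta

REGISTRY_TSV = "seed_registry.tsv"
SEED_FASTA = "seed_sequences_synthetic.fasta"
DOMAIN_FASTA = "pfam_domains_synthetic.fasta"


class ModelPolicy(enum.Enum):
    """How the homolog-detection model(s) for a seed enzyme are obtained."""

    #: One full-length profile built de novo from a homolog set.
    DE_NOVO_FULL = "de_novo_full"
    #: One profile per listed Pfam domain, taken from a domain-model store.
    PFAM_DOMAINS = "pfam_domains"


@dataclass(frozen=True)
class SeedEnzyme:
    """One registry row: a reference enzyme and its modelling policy."""

    enzyme_id: str
    gene: str
    enzyme_name: str
    reference_species: str
    uniprot_id: str
    sequence: str
    pfam_domain_ids: tuple[str, ...]
    model_policy: ModelPolicy
    #: Start offset of each Pfam domain within ``sequence`` (per-domain policy
    #: only; empty for de novo rows).  Domains are ``domain_length`` long.
    domain_starts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.enzyme_id}: empty sequence")
        if not self.pfam_domain_ids:
            raise ValueError(f"{self.enzyme_id}: no Pfam domains listed")
        if self.model_policy is ModelPolicy.PFAM_DOMAINS and len(
            self.domain_starts
        ) != len(self.pfam_domain_ids):
            raise ValueError(
                f"{self.enzyme_id}: per-domain policy needs one start per domain"
            )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedRegistry:
    """Ordered collection of :class:`SeedEnzyme` plus the shared domain sequences."""

    enzymes: tuple[SeedEnzyme, ...]
    #: Pfam id -> synthetic domain sequence (per-domain policy enzymes only).
    domain_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError("registry must contain at least one enzyme")
        ids = [e.enzyme_id for e in self.enzymes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate enzyme ids in registry")

    def __iter__(self):
        return iter(self.enzymes)

    def __len__(self) -> int:
        return len(self.enzymes)

    def __getitem__(self, enzyme_id: str) -> SeedEnzyme:
        for e in self.enzymes:
            if e.enzyme_id == enzyme_id:
                return e
        raise KeyError(enzyme_id)

    @property
    def enzyme_ids(self) -> list[str]:
        return [e.enzyme_id for e in self.enzymes]

    def subset(self, enzyme_ids: list[str]) -> "SeedRegistry":
        """Registry restricted to ``enzyme_ids`` (order preserved), e.g. for
        small benchmark cohorts."""
        keep = [self[i] for i in enzyme_ids]
        needed = {d for e in keep if e.model_policy is ModelPolicy.PFAM_DOMAINS for d in e.pfam_domain_ids}
        return SeedRegistry(
            enzymes=tuple(keep),
            domain_sequences={k: v for k, v in self.domain_sequences.items() if k in needed},
        )


def _read_data_text(name: str) -> str:
    return resources.files("reservescan").joinpath("data", name).read_text()


def load_registry() -> SeedRegistry:
    """Load the packaged enzyme registry with its synthetic sequences."""
    seqs = dict(read_fasta(_read_data_text(SEED_FASTA).splitlines()))
    domain_seqs = dict(read_fasta(_read_data_text(DOMAIN_FASTA).splitlines()))
    enzymes = []
    lines = _read_data_text(REGISTRY_TSV).splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        enzyme_id = row["enzyme_id"]
        starts = tuple(int(s) for s in row["domain_starts"].split(",") if s)
        enzyme = SeedEnzyme(
            enzyme_id=enzyme_id,
            gene=row["gene"],
            enzyme_name=row["enzyme_name"],
            reference_species=row["reference_species"],
            uniprot_id=row["uniprot_id"],
            sequence=seqs[enzyme_id],
            pfam_domain_ids=tuple(row["pfam_domain_ids"].split(",")),
            model_policy=ModelPolicy(row["model_policy"]),
            domain_starts=starts,
        )
        if enzyme.length_aa != int(row["length_aa"]):
            raise ValueError(f"{enzyme_id}: sequence length mismatch with registry")
        enzymes.append(enzyme)
    return SeedRegistry(enzymes=tuple(enzymes), domain_sequences=domain_seqs)
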