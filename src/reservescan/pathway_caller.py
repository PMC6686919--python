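"""Pathway presence/absence calling from enzyme copy counts.

A pathway is called present in a proteome iff every required enzyme has at
least one accepted homolog (set-based AND semantics — no synteny or operon
structure is considered).  Polyphosphate metabolism gets a three-way status
(complete / partial / absent) because both the all-three and none-of-three
cohorts are biologically meaningful contrasts, and PHA synthase is classified
into its two domain-defined groups.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError, InvalidParameterError
from .homology_search import PHAC_ANY, EnzymeProfile

POLYP_ENZYMES = ("ppk1", "ppk2", "ppx")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named set of enzymes that must all be present (AND semantics)."""

    pathway_id: str
    required_enzymes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.required_enzymes:
            raise InvalidParameterError(f"pathway {self.pathway_id!r} has no required enzymes")


class PhacGroup(enum.Enum):
    """PHA synthase classification by Pfam domain family."""

    GROUP1 = "group1"  # Abhydrolase_1 (PF00561)
    GROUP2 = "group2"  # PhaC_N (PF07167)
    BOTH = "both"
    NONE = "none"


def default_pathways(accept_gh57_branching: bool = False) -> list[PathwayDefinition]:
    """The screened pathway set for the five energy reserves.

    The branching-enzyme slot of both glycogen routes defaults to the common
    bacterial GH13 family; with ``accept_gh57_branching`` the archaeal-type
    GH57 family also satisfies it (via the derived ``glgB_any`` count).
    """
    glgb = "glgB_any" if accept_gh57_branching else "glgB_gh13"
    return [
        PathwayDefinition("classical_glycogen", frozenset({"glgC", "glgA", glgb}),
                          "Classical glycogen synthesis (GlgC-GlgA-GlgB)"),
        PathwayDefinition("trehalose_glycogen", frozenset({"treS", "pep2", "glgE", glgb}),
                          "Trehalose/GlgE glycogen synthesis (TreS-Pep2-GlgE-GlgB)"),
        PathwayDefinition("pha_abc", frozenset({"phaA", "phaB", PHAC_ANY}),
                          "Classical PHA synthesis (PhaA-PhaB-PhaC)"),
        PathwayDefinition("polyp_complete", frozenset(POLYP_ENZYMES),
                          "Complete polyP metabolism (PPK1, PPK2, PPX)"),
        PathwayDefinition("we_tag", frozenset({"ws_dgat"}),
                          "Wax ester / TAG synthesis (WS/DGAT)"),
        PathwayDefinition("pdat", frozenset({"pdat"}),
                          "Acyl-CoA-independent TAG synthesis (PDAT)"),
        PathwayDefinition("rv3032_glucan", frozenset({"rv3032"}),
                          "Rv3032 alpha-1,4-glucan elongation"),
        PathwayDefinition("pha_fabg", frozenset({"fabG"}), "PHA synthesis via FabG"),
        PathwayDefinition("pha_phaj", frozenset({"phaJ"}), "PHA synthesis via PhaJ"),
        PathwayDefinition("pha_fabd", frozenset({"fabD"}), "PHA synthesis via FabD"),
        PathwayDefinition("pha_sucd_4hbd_orfz", frozenset({"sucD", "4hbD", "orfZ"}),
                          "PHA synthesis via SucD-4HbD-OrfZ"),
    ]


# ---------------------------------------------------------------------------
# per-proteome calls
# ---------------------------------------------------------------------------


def _counts_with_derived(profile: EnzymeProfile) -> dict[str, int]:
    counts = dict(profile.copy_counts)
    if "glgB_gh13" in counts and "glgB_gh57" in counts:
        counts.setdefault("glgB_any", counts["glgB_gh13"] + counts["glgB_gh57"])
    return counts


def call_pathway(profile: EnzymeProfile, definition: PathwayDefinition) -> bool:
    """True iff every required enzyme has copy count >= 1."""
    counts = _counts_with_derived(profile)
    for enzyme_id in definition.required_enzymes:
        if enzyme_id not in counts:
            raise IntegrityError(
                f"profile {profile.proteome_id!r} lacks enzyme {enzyme_id!r} "
                f"required by pathway {definition.pathway_id!r}"
            )
    return all(counts[e] >= 1 for e in definition.required_enzymes)


def classify_phac(profile: EnzymeProfile) -> PhacGroup:
    """Classify the proteome's PHA synthase complement by domain family."""
    counts = profile.copy_counts
    g1 = counts.get("phaC_group1", 0) >= 1
    g2 = counts.get("phaC_group2", 0) >= 1
    if g1 and g2:
        return PhacGroup.BOTH
    if g1:
        return PhacGroup.GROUP1
    if g2:
        return PhacGroup.GROUP2
    return PhacGroup.NONE


def polyp_status(profile: EnzymeProfile) -> str:
    """Three-way polyP status: 'complete' (all of PPK1/PPK2/PPX), 'absent'
    (none of the three) or 'partial' (anything else)."""
    present = [profile.copy_counts.get(e, 0) >= 1 for e in POLYP_ENZYMES]
    if all(present):
        return "complete"
    if not any(present):
        return "absent"
    return "partial"


# ---------------------------------------------------------------------------
# the matrix (Table S1 analog)
# ---------------------------------------------------------------------------


@dataclass
class PathwayCallMatrix:
    """Proteomes x {enzyme copy counts, pathway booleans, PhaC group, polyP
    status, proteome size} — the distribution matrix the screen produces."""

    data: pd.DataFrame
    enzyme_ids: list[str]
    pathway_ids: list[str]

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.data, path)

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(self.data.to_json(orient="records", indent=1))


def build_matrix(
    profiles: list[EnzymeProfile],
    definitions: list[PathwayDefinition] | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> PathwayCallMatrix:
    """Assemble the per-proteome call matrix.

    One row per proteome with enzyme copy-number columns, one boolean column
    per pathway definition, the three-way polyP status and the PhaC group.
    ``taxonomy`` (proteome_id, taxid, ...) is merged in when provided.
    """
    if definitions is None:
        definitions = default_pathways()
    ids = [p.proteome_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate proteome ids: {dupes}")
    enzyme_ids = sorted({e for p in profiles for e in p.copy_counts})
    rows = []
    for p in profiles:
        row: dict = {"proteome_id": p.proteome_id, "proteome_size": p.proteome_size}
        counts = _counts_with_derived(p)
        for e in enzyme_ids:
            row[e] = counts.get(e, 0)
        for d in definitions:
            row[d.pathway_id] = call_pathway(p, d)
        row["polyp_status"] = polyp_status(p)
        row["phac_group"] = classify_phac(p).value
        rows.append(row)
    df = pd.DataFrame(rows)
    if taxonomy is not None:
        df = taxonomy.merge(df, on="proteome_id", how="right")
    return PathwayCallMatrix(
        data=df,
        enzyme_ids=enzyme_ids,
        pathway_ids=[d.pathway_id for d in definitions],
    )


def summarize_counts(matrix: PathwayCallMatrix) -> pd.DataFrame:
    """Presence summary per enzyme and per pathway.

    Returns a table with columns (kind, id, n_present, n_total, percentage);
    percentages are ``100 * n_present / n_total`` rounded to 2 decimals.
    """
    if len(matrix) == 0:
        raise InvalidParameterError("cannot summarize an empty matrix")
    n_total = len(matrix)
    rows = []
    for e in matrix.enzyme_ids:
        n = int((matrix.data[e] >= 1).sum())
        rows.append(("enzyme", e, n, n_total, round(100.0 * n / n_total, 2)))
    for pid in matrix.pathway_ids:
        n = int(matrix.data[pid].sum())
        rows.append(("pathway", pid, n, n_total, round(100.0 * n / n_total, 2)))
    for status in ("complete", "partial", "absent"):
        n = int((matrix.data["polyp_status"] == status).sum())
        rows.append(("polyp_status", status, n, n_total, round(100.0 * n / n_total, 2)))
    return pd.DataFrame(
        rows, columns=["kind", "id", "n_present", "n_total", "percentage"]
    )
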