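"""Regenerate the packaged synthetic seed-enzyme data files.

Produces, under src/reservescan/data/:
  seed_registry.tsv               enzyme metadata (genes, accessions, domains)
  seed_sequences_synthetic.fasta  synthetic stand-ins for the reference sequences
  pfam_domains_synthetic.fasta    one synthetic 100-residue sequence per Pfam
                                  domain used by the per-domain model policy

The sequences are random but deterministic (fixed seed below); lengths and
domain compositions follow the published enzyme table.  Enzymes under the
per-domain policy are laid out as  linker - domain - linker - ... - domain -
linker  with the leftover length split evenly across linkers, and a Pfam
domain shared between two enzymes embeds the identical synthetic sequence in
both.  Run from the repository root:  python scripts/make_seed_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from reservescan.alphabet import random_protein  # noqa: E402

SEED = 811_231
DOMAIN_LENGTH = 100

# enzyme_id, gene, enzyme_name, reference_species, uniprot_id, length_aa,
# pfam_domain_ids, model_policy
TABLE = [
    ("ppk1", "ppk1", "Polyphosphate kinase", "Escherichia coli", "E7QTB5",
     688, ["PF02503", "PF13090", "PF17941", "PF13089"], "de_novo_full"),
    ("ppk2", "ppk2", "Polyphosphate kinase 2", "Mycobacterium tuberculosis",
     "O05877", 295, ["PF03976"], "pfam_domains"),
    ("ppx", "ppx", "Ppx/GppA phosphatase", "Escherichia coli", "P0AFL6",
     513, ["PF02541"], "pfam_domains"),
    ("glgC", "glgC", "Glucose-1-phosphate adenylyltransferase",
     "Escherichia coli", "P0A6V1", 431, ["PF00483"], "pfam_domains"),
    ("glgA", "glgA", "Glycogen synthase", "Escherichia coli", "P0A6U8",
     477, ["PF08323", "PF00534"], "pfam_domains"),
    ("glgB_gh57", "glgB", "Alpha-1,4-glucan branching enzyme (GH57)",
     "Thermococcus kodakaraensis", "Q5JDJ7", 675,
     ["PF09210", "PF03065", "PF14520"], "de_novo_full"),
    ("glgB_gh13", "glgB", "Alpha-1,4-glucan branching enzyme (GH13)",
     "Escherichia coli", "P07762", 728,
     ["PF02922", "PF00128", "PF02806"], "de_novo_full"),
    ("treS", "treS", "Trehalose synthase/amylase",
     "Mycobacterium tuberculosis", "P9WQ19", 601,
     ["PF00128", "PF16657"], "de_novo_full"),
    ("pep2", "pep2", "Maltokinase", "Mycobacterium tuberculosis", "Q7DAF6",
     455, ["PF18085"], "de_novo_full"),
    ("glgE", "glgE", "Alpha-1,4-glucan: maltose-1-phosphate maltosyltransferase",
     "Mycobacterium tuberculosis", "P9WQ17", 701,
     ["PF00128", "PF11896"], "de_novo_full"),
    ("rv3032", "Rv3032", "Glycogen synthase (Rv3032)",
     "Mycobacterium tuberculosis", "P9WMY9", 414,
     ["PF13439", "PF00534"], "pfam_domains"),
    ("phaA", "phaA", "Acetyl-CoA acetyltransferase", "Cupriavidus necator",
     "P14611", 246, ["PF02803", "PF00108"], "pfam_domains"),
    ("phaB", "phaB", "Acetoacetyl-CoA reductase", "Cupriavidus necator",
     "P14697", 393, ["PF00106"], "pfam_domains"),
    ("phaC_group1", "phaC", "Poly(3-hydroxyalkanoate) polymerase subunit C (Group 1)",
     "Allochromatium vinosum", "P45370", 355, ["PF00561"], "pfam_domains"),
    ("phaC_group2", "phaC", "Class II poly(R)-hydroxyalkanoic acid synthase (Group 2)",
     "Pseudomonas aeruginosa", "Q51513", 559, ["PF07167"], "pfam_domains"),
    ("fabG", "fabG", "3-Oxoacyl-[acyl-carrier-protein] reductase",
     "Escherichia coli", "P0AEK2", 244, ["PF13561"], "pfam_domains"),
    ("phaJ", "phaJ", "(R)-Enoyl-CoA hydratase/enoyl-CoA hydratase I",
     "Pseudomonas aeruginosa", "Q9LBK2", 156, ["PF01575"], "pfam_domains"),
    ("fabD", "fabD", "Malonyl CoA-acyl carrier protein transacylase",
     "Escherichia coli", "P0AAI9", 209, ["PF00698"], "pfam_domains"),
    ("sucD", "sucD", "Succinic semialdehyde dehydrogenase",
     "Clostridium kluyveri", "P38947", 453, ["PF00171"], "pfam_domains"),
    ("4hbD", "4hbD", "NAD-dependent 4-hydroxybutyrate dehydrogenase",
     "Clostridium kluyveri", "P38945", 371, ["PF00465"], "pfam_domains"),
    ("orfZ", "orfZ", "4-Hydroxybutyrate CoA-transferase",
     "Clostridium kluyveri", "A0A1L5FD42", 437,
     ["PF02550", "PF13336"], "pfam_domains"),
    ("pdat", "PDAT", "Phospholipid:diacylglycerol acyltransferase",
     "Saccharomyces cerevisiae", "P40345", 661, ["PF02450"], "pfam_domains"),
    ("ws_dgat", "wax-dgaT",
     "Wax ester synthase/acyl-CoA:diacylglycerol acyltransferase",
     "Acinetobacter baylyi", "Q8GGG1", 458,
     ["PF06974", "PF03007"], "pfam_domains"),
]


def main() -> None:
    rng = np.random.default_rng(SEED)
    data_dir = ROOT / "src" / "reservescan" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    # One shared synthetic sequence per Pfam domain under the per-domain policy.
    domain_ids = []
    for row in TABLE:
        if row[7] == "pfam_domains":
            for d in row[6]:
                if d not in domain_ids:
                    domain_ids.append(d)
    domain_seq = {d: random_protein(DOMAIN_LENGTH, rng) for d in domain_ids}

    registry_rows = []
    seed_records = []
    for enzyme_id, gene, name, species, uniprot, length, domains, policy in TABLE:
        if policy == "pfam_domains":
            k = len(domains)
            leftover = length - k * DOMAIN_LENGTH
            assert leftover >= 0, enzyme_id
            base, extra = divmod(leftover, k + 1)
            linkers = [base + (1 if i < extra else 0) for i in range(k + 1)]
            parts, starts, pos = [], [], 0
            for i, d in enumerate(domains):
                parts.append(random_protein(linkers[i], rng) if linkers[i] else "")
                pos += linkers[i]
                starts.append(pos)
                parts.append(domain_seq[d])
                pos += DOMAIN_LENGTH
            parts.append(random_protein(linkers[k], rng) if linkers[k] else "")
            seq = "".join(parts)
            starts_str = ",".join(str(s) for s in starts)
        else:
            seq = random_protein(length, rng)
            starts_str = ""
        assert len(seq) == length, enzyme_id
        seed_records.append((enzyme_id, seq))
        registry_rows.append(
            [enzyme_id, gene, name, species, uniprot, str(length),
             ",".join(domains), policy, starts_str]
        )

    header = ["enzyme_id", "gene", "enzyme_name", "reference_species",
              "uniprot_id", "length_aa", "pfam_domain_ids", "model_policy",
              "domain_starts"]
    with (data_dir / "seed_registry.tsv").open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in registry_rows:
            fh.write("\t".join(row) + "\n")

    from reservescan.io import write_fasta

    write_fasta(seed_records, data_dir / "seed_sequences_synthetic.fasta")
    write_fasta(sorted(domain_seq.items()), data_dir / "pfam_domains_synthetic.fasta")
    print(f"wrote {len(seed_records)} seeds, {len(domain_seq)} domains -> {data_dir}")


if __name__ == "__main__":
    main()
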