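# reservescan

Profile-model screening of bacterial proteomes for the key enzymes of the
five major **energy reserves** — polyphosphate (polyP), glycogen, wax ester
(WE), triacylglycerol (TAG) and polyhydroxyalkanoates (PHA) — with pathway
presence/absence calling, proteome-size statistics and phylogeny-annotation
export. It is aimed at comparative genomicists who want to ask, across a
cohort of proteomes: *which organisms can still make which energy reserve,
and is losing that capacity associated with genome reduction?*

## What it computes

Starting from a registry of 23 seed enzymes (gene, reference species,
UniProt accession, length, Pfam domain composition), the pipeline:

1. **Builds profile models** per enzyme: dereplicate its homolog set at 98%
   identity, align progressively, trim ragged termini (column occupancy
   < 0.5), and estimate a position-specific match/insert/delete profile with
   background-weighted pseudocounts. Enzymes with more than two non-redundant
   domains (PPK1, both GlgB families) and the trehalose-route enzymes (TreS,
   Pep2, GlgE) get one full-length de novo model; the rest get one model per
   Pfam domain.
2. **Screens proteomes**: each protein is scored by best local Viterbi
   alignment (log-odds, bits); scores become E-values through a Gumbel fit
   to random-sequence scores; a hit is accepted iff

   `E < 1e-10` **and** `query coverage > 60%`

   (both strict; coverage = aligned model span / model length). Copy number
   of an enzyme = number of distinct accepted proteins; per-domain enzymes
   require all their domain models to hit the same protein.
3. **Calls pathways** by AND-completeness — e.g. classical glycogen
   {GlgC, GlgA, GlgB-GH13}, trehalose route {TreS, Pep2, GlgE, GlgB-GH13},
   PhaABC {PhaA, PhaB, PhaC (either synthase group)} — plus a three-way polyP
   status (complete / partial / absent) and the PhaC group
   (Abhydrolase_1-type vs PhaC_N-type).
4. **Compares proteome sizes** of pathway-positive vs pathway-negative
   groups with an unpaired two-tailed Student t test (p < 0.05; Welch
   optional).
5. **Exports** a taxonomy tree (Newick, internal labels, lexicographic
   sibling order) and per-leaf annotation layers (simple-bar copy counts and
   proteome sizes, binary pathway calls) in the iTOL plain-text dialect.

Because real UniProt reference proteomes require a database download, the
package ships a first-class **synthetic cohort generator**: proteomes of
controlled size containing planted seed-enzyme homologs at controlled
identity among random decoys, toy clades with clade-restricted pathway
complements, and a configurable proteome-size effect between
pathway-positive and pathway-negative groups. Every downstream stage is
tested against this planted ground truth. The packaged seed sequences are
synthetic stand-ins at the published lengths and domain layouts (see
`docs/methods.md`).

## Worked example

```python
from reservescan.pipeline import run_benchmark
from reservescan.synthetic_cohort import default_cohort_config
from reservescan.reserve_stats import report

result = run_benchmark(seed=1, cohort_config=default_cohort_config(rng_seed=1, n_proteomes=30))
print(result.summary[result.summary.kind == "pathway"].to_string(index=False))
print(report(result.comparisons))
```

prints (abridged):

```
   kind                 id  n_present  n_total  percentage
pathway classical_glycogen         16       30       53.33
pathway trehalose_glycogen          8       30       26.67
pathway            pha_abc         16       30       53.33
pathway     polyp_complete         17       30       56.67
pathway             we_tag         17       30       56.67
...
Proteome-size contrasts (two-tailed t test, alpha = 0.05):
  classical_glycogen: 78 proteins/proteome (n=16) with vs 70 (n=14) without; t=3.319, df=28.0, p=0.00251 (significant)
  trehalose_glycogen: 77 proteins/proteome (n=8) with vs 74 (n=22) without; t=1.015, df=28.0, p=0.319 (not significant)
  ...
  polyp: 78 proteins/proteome (n=17) with vs 61 (n=6) without; t=8.709, df=21.0, p=2.06e-08 (significant)
```

Reading it: the generator planted the classical glycogen pathway in the
proteobacteria- and firmicutes-like clades (16 of 30 proteomes, 53.33%) and
confined the trehalose route to the actinobacteria-like clade (8 of 30);
the screen recovered exactly those complements. With the default
`size_effect = 0` the small but significant size differences reflect the
planted enzymes themselves — complement-carrying proteomes contain a few
extra proteins, and the reduced mollicute-like clade (the polyP-absent
group) carries none.

The same pipeline is available from the shell:

```sh
reservescan --seed 1 --out run1 all          # simulate → models → screen → call → stats → viz
reservescan --config my.yaml --out run2 screen
```

Each stage writes its artifacts (`cohort/`, `models.json`, `hits.tsv`,
`matrix.tsv`, `summary.tsv`, `comparisons.tsv`, `tree.nwk`, `layers/`) and a
provenance manifest; re-running with the same seed reproduces the matrix
byte-for-byte.

## Layout

```
src/reservescan/
  registry.py          seed-enzyme registry (packaged synthetic sequences)
  synthetic_cohort.py  cohort generator with planted ground truth
  model_factory.py     dereplication, MSA, trimming, profile estimation
  homology_search.py   Viterbi scoring, Gumbel E-values, hit filtering, copy counts
  pathway_caller.py    pathway calls, PhaC groups, the per-proteome matrix
  reserve_stats.py     proteome-size contrasts (Student/Welch t)
  taxonomy_viz.py      taxonomy Newick + iTOL-dialect annotation layers
  cli.py               `reservescan` command-line pipeline
docs/methods.md        model, parameters, design choices, limitations
```
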