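# Methods

## Overview

`reservescan` implements a comparative-proteomics screen for the key enzymes
of the five bacterial energy reserves — polyphosphate (PPK1/PPK2/PPX),
glycogen (classical GlgC–GlgA–GlgB route, trehalose TreS–Pep2–GlgE–GlgB
route, Rv3032, and the GH13/GH57 branching-enzyme families), wax ester and
triacylglycerol (WS/DGAT, PDAT), and polyhydroxyalkanoates (PhaA/PhaB/PhaC
plus the FabG, PhaJ, FabD and SucD–4HbD–OrfZ routes). A registry of 23 seed
enzymes carries, per enzyme, the reference species, gene, UniProt accession,
sequence length, Pfam domain composition and a model-construction policy.
Proteomes are screened with position-specific profile models; accepted
homologs become per-proteome copy counts, copy counts become pathway
presence/absence calls, and pathway calls feed proteome-size contrasts and
phylogeny-annotation exports.

The packaged seed and domain sequences are **synthetic stand-ins**: they
reproduce the published lengths and domain layouts (including the PF00534
domain shared by the two glycogen synthases) but are randomly generated, so
the pipeline is fully exercised offline. Swapping in real sequences is just a
matter of replacing the registry FASTA files.

## Profile models

Two policies, frozen per registry row:

* **DE_NOVO_FULL** — one full-length model built from the enzyme's homolog
  set. Applied to ppk1 and both glgB families (more than two non-redundant
  domains) and to treS, pep2 and glgE (short or uncharacterised domains).
* **PFAM_DOMAINS** — one model per annotated Pfam domain, drawn from a
  domain-model store. With no offline access to the Pfam database, the store
  is built de novo from synthetic homolog sets of per-domain canonical
  sequences (100 aa each, embedded in the seeds between random linkers).

Model construction follows the standard protein-family recipe:

1. **Dereplication** at 98% identity, greedy in input order: a sequence is
   kept iff its identity to every kept representative is ≤ 0.98. Identity is
   computed on a global alignment that maximises matched columns and then
   minimises gap columns (both packed into one DP objective), giving a
   symmetric, deterministic comparator; identity = matches / alignment
   columns.
2. **Progressive multiple alignment**: guide order by pairwise identity
   (closest pair first, then nearest-by-average); each sequence is aligned
   to the growing column profile with column scores equal to the fraction of
   matching residues and a linear gap penalty of −0.6. Deleting gaps from
   any row recovers its input sequence.
3. **Terminus trimming**: leading and trailing columns with non-gap
   occupancy < 0.5 are removed (interior columns never are) — a
   deterministic stand-in for the manual trimming of ragged alignment ends.
4. **Profile estimation**: match states are columns with occupancy ≥ 0.5.
   Match emissions use background-weighted pseudocounts,
   `(count + w·q) / (n_residues + w)` with weight `w = 1` and uniform
   background `q`; transitions are estimated the same way against fixed
   priors (M→{M,I,D} = 0.9/0.05/0.05, I→{M,I} = 0.8/0.2,
   D→{M,D} = 0.7/0.3). Inserts emit the background. I↔D transitions are not
   modelled (classical 7-transition profile topology); an insert run ending
   before a gap column is folded into I→I, a cold corner for the nearly
   gap-free synthetic alignments.

## Scoring and E-values

A protein is scored by the best **local Viterbi alignment** against the
profile: log-odds in bits against the background null, begin transitions
into any match state at a cost of `log2(m)` (uniform entry), free exit from
any match state, and flanking residues emitted by the null (so the score is
invariant to unrelated sequence around the hit). Paths start and end on
match states. The implementation is a numba kernel that also propagates the
alignment's start coordinates, yielding the query and target spans
(0-based, half-open). An exhaustive path-enumeration oracle (≤ 6 match
states, ≤ 12 residues) verifies the kernel exactly. This is deliberately not
a full Plan7 implementation — no multi-hit mode, no forward/posterior
decoding.

E-values use the standard Gumbel tail: each model is calibrated by scoring
`n_random = 200` background sequences of the model's length and fitting a
Gumbel by maximum likelihood (profile-likelihood root for the scale via
bracketed root finding — exactly shift- and scale-equivariant), then
`E = n_targets · exp(−λ(S − µ))`, capped at `n_targets`. `n_targets`
defaults to the protein count of the searched proteome (each proteome is an
independent search); a fixed-N policy is available for cross-proteome
comparability.

## Hit acceptance and copy counting

A hit is accepted iff **E-value < 1e-10** (strict) **and query coverage
> 60%** (strict), where coverage is the aligned span on the model divided by
the model's query length — the query, not the target, is the denominator.
A protein contributes at most one copy per enzyme; per-domain enzymes
require accepted hits from **all** their domain models on the same protein
(an OR rule would inflate counts, e.g. the shared PF00534 domain would make
every GlgA also count as Rv3032). A derived `phaC_any` count (either
synthase group) supports the PhaABC pathway call. Raw hits down to E ≤ 10
are retained so thresholds can be tightened without re-scoring; tightening
either threshold provably never increases a copy count.

## Pathway calling

Set-based AND semantics: a pathway is present iff every required enzyme has
count ≥ 1. Definitions: classical glycogen {glgC, glgA, glgB-GH13},
trehalose route {treS, pep2, glgE, glgB-GH13}, PhaABC {phaA, phaB,
phaC_any}, complete polyP {ppk1, ppk2, ppx}, the single-enzyme routes
(WS/DGAT, PDAT, Rv3032, FabG, PhaJ, FabD) and {sucD, 4hbD, orfZ}. The
branching-enzyme slot defaults to the bacterial-dominant GH13 family; a
switch lets GH57 satisfy it. PolyP gets a three-way status (complete /
partial / absent) because both extreme cohorts are analysed; PhaC synthases
are classified GROUP1 (Abhydrolase_1) / GROUP2 (PhaC_N) / BOTH / NONE.

## Statistics

Proteome sizes of pathway-positive vs pathway-negative groups are compared
with an unpaired two-tailed t test, pooled-variance Student form by default
(Welch with Satterthwaite df as an option, since group variances plausibly
differ), significance at p < 0.05. The polyP contrast compares
complete vs absent, excluding partial complements. Degenerate inputs: two
zero-variance groups give t = 0, p = 1 when means agree and t = ±∞, p = 0
otherwise; groups below two members are an error. No multiple-testing
correction is applied across pathways.

## Synthetic cohorts

The generator emulates the statistical structure of a reference-proteome
screen, not sequence evolution:

* **Planted homologs** are full-length point-substituted copies of the seed
  with Hamming identity exactly `round(identity·L)/L` — no indels by
  default, keeping the identity contract exact. Identities are drawn
  uniformly from a configured range (default 0.85–0.95, comfortably inside
  the detection range of the models, which are themselves built from
  synthetic homologs at 0.80–0.95).
* **Decoys** are i.i.d. residues from a stated background (uniform by
  default — maximally dissimilar to any profile, making false-positive
  checks conservative; a Robinson–Robinson table is available). Default
  cohort: 100 proteomes, decoy counts normal(65, 5) clipped at 50, decoy
  lengths normal(250, 60) clipped at 60. These sizes keep a full benchmark
  (model building + screening 100 proteomes against 28 models) at a few
  minutes on one core.
* **Clades**: four toy clades with complements caricaturing the reported
  biology — a proteobacteria-like clade (classical glycogen, full polyP,
  PhaABC with Group-2 synthase, WS/DGAT, PDAT), an actinobacteria-like clade
  (trehalose route, Rv3032, Group-1 synthase, two WS/DGAT copies), a
  firmicutes-like clade (classical glycogen with both GlgB families, partial
  polyP, no WS/DGAT) and a reduced mollicutes-like clade with nothing.
  The trehalose route is thereby clade-restricted by construction.
* **Size effect**: an integer added to the decoy count of every
  pathway-positive proteome, so enzyme content and proteome size are
  independently controllable. Monte-Carlo statistics (type-I error at 1000
  null cohorts, power at a planted effect of 2000 with group SD 300 and
  n = 200/group) sample the truth tables directly without synthesising
  sequences — the t-test inputs are identical either way.

Passing tests on these cohorts demonstrate the pipeline's mechanics
(detection at the configured identities, exact truth recovery, threshold
behaviour, statistical calibration); they do not demonstrate performance on
real proteomes, where homologs have indels, domain rearrangements and
compositional bias that the generator deliberately omits.

## Visualization export

The taxonomy tree is a prefix tree over lineage rank paths (polytomies
allowed, unary chains kept), emitted as Newick with internal labels, no
branch lengths, and lexicographic sibling order for byte-stable output.
Matrix columns are projected onto leaves as plain-text annotation datasets
(simple-bar for copy counts and proteome sizes, binary for pathway calls)
with the `SEPARATOR COMMA / DATASET_LABEL / COLOR / DATA` header block that
circular-tree viewers consume. No images are rendered.

## Numerical choices and tie-breaking

* Alignment DP ties prefer pairing over gaps, then consuming the new
  sequence's residue; the identity comparator's objective makes its value
  tie-independent.
* Viterbi ties resolve toward the entry/earlier-predecessor branch; spans
  may differ between tied optima but scores (the tested quantity) do not.
* Gumbel fitting brackets the scale within [sd/100, 100·sd], expanding if
  needed; zero-variance samples are a calibration error.
* All randomness flows through explicit `numpy` Generators; per-model
  calibration streams derive from (seed, crc32(enzyme id), model index), so
  results are independent of process hash randomisation.
* Ambiguous residues (X/B/Z/U/O/J) score as background (log-odds 0)
  everywhere.

## Known limitations

* Single best local hit per protein-model pair (no multi-domain envelope
  resolution within one protein; irrelevant for counting distinct proteins).
* Gumbel calibration at n = 200 gives E-value accuracy adequate for a
  10-orders-of-magnitude threshold margin, not for E-values near 1.
* The progressive aligner is identity-scored (no substitution matrix) — fine
  for the ≥ 65% pairwise identities of synthesized homolog sets, weak for
  remote homology alignment.
* Degradation pathways (GlgP/GlgX, PhaZ) are out of scope; only synthesis
  and the listed degradation enzymes of polyP are modelled.
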