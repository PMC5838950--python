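# Methods

This note documents the models, scoring rules, parameters and design
choices behind `sitemine`, and what its synthetic benchmarks do and do not
show about real literature data.

## Mining model

The unit of evidence is an abstract retrieved for a protein–protein
complex, tagged with its query provenance: an **AND-query** abstract
matched both partner names, an **OR-query** abstract matched at least one.
AND provenance is treated as stronger evidence throughout (confidence
weights, re-ranking precedence).  Within an abstract the unit of analysis
is the **residue-containing sentence**; its immediate neighbours are the
**context sentences**.

### Residue-mention grammar

The published protocol does not specify its mention grammar, so the
package defines one and treats it as part of the method:

- case-insensitive 3-letter codes and full amino-acid names, fused to the
  number or separated by a space/hyphen (`Glu67`, `Glu 67`, `Glu-67`,
  `glutamate 67`);
- upper-case 1-letter codes fused to digits (`E67`) — a deliberate
  superset that can fire on identifiers like `T4`; disable with
  `one_letter=False` where precision matters;
- mutation notation (`E67A`, `Glu67Ala`) yields the wild-type residue
  only, since the wild type is what sits in the structure;
- a trailing upper-case letter directly after the number that is not an
  amino-acid code is a chain hint (`Glu67B` → chain B).

Residue numbers are author numbering exactly as printed; any renumbering
happens only when mapping onto structures.  Sentence segmentation is
rule-based (split at `.?!` before an upper-case/digit/bracket opener,
protected abbreviation list) so extraction is deterministic and
reproducible without model downloads.

### Structural validation

A mention must (i) match a residue of the same 3-letter name and author
number in the complex's PDB file (the chain hint, when present, restricts
the search) and (ii) lie on the protein surface.  Surface means relative
solvent-accessible area ≥ 0.05, computed with Shrake–Rupley (probe 1.4 Å,
960 points/atom, heavy atoms only) and normalised by extended-state
reference areas (Tien et al. 2013 theoretical maxima).  The surface
criterion and threshold are this package's choice — the original protocol
does not document one — and both are configurable; 0.05 is permissive on
purpose, so only clearly buried residues are discarded.  Interface
residues (the evaluation ground truth and the source of reference
constraints) are residues with any heavy atom within **6 Å** of the
partner.  Unbound chains are matched to bound chains by global sequence
alignment (identity scoring, affine gaps −2/−0.5), erroring below 30%
identity; aligned, type-identical positions define the residue map.

## NLP filters

**Dictionary look-up.** A sentence's residues are kept iff a PPI+ive
lemma is spotted.  Lemmas are stems: all-lowercase lemmas of length ≥ 4
match case-insensitively as prefixes anchored at the token start
(`interfac` → "interface", "interfacial"); short or mixed-case lemmas
(`Fc`, `IgG1`, `dCTP`) require an exact case-sensitive token match so they
do not over-fire.  The packaged dictionary has 16 PPI+ive and 36 PPI-ive
lemmas.

**Semantic similarity.** Every sentence word is compared with the concept
words *touch* and *site* under one of three measures, and the sentence's
residues are kept iff any score **strictly** exceeds the measure's
threshold: Lesk 20, Lin 0.2, Path 0.11 ("exceeded" is read as strict; the
aggregation over the two concept words is max, recorded as configurable).
The shipped provider is a deterministic ~50-word synset forest built for
offline testing: four hypernym trees (contact phenomena, chemical
processes, substances, attributes) with per-synset glosses and corpus
counts.  Path similarity is 1/(1+d) over the hypernym graph and is
undefined across trees; Lin uses information content from the synthetic
counts; Lesk is an extended gloss overlap (sum of squared lengths of
maximal shared phrases over own + hypernym + hyponym glosses).  Its scores
are internally consistent but have no quantitative relationship to
WordNet's; a WordNet-backed provider can be plugged in through the same
one-method contract.

**Parse-tree scoring (Method 1).** For residue X in a parsed sentence,

    S_X = Σ_i 1/d⁺_Xi − Σ_j 1/d⁻_Xj

where the sums run over every *occurrence* of a PPI+ive / PPI-ive keyword
among the leaves, d is the edge-count distance from the residue's head
leaf (for multi-token mentions, the name token), and the residue's own
leaf never counts as a keyword.  A mention is kept iff S_X > 0.25
(strict).  Occurrence- rather than type-level summation was chosen because
the score indexes words, not lemmas.  Sentences without a parse tree
abstain by default (mention passes, with a warning); `--strict-trees`
drops instead.  Trees come from a sidecar file of bracketed S-expressions
or any text→S-expression parser callable; no parser is bundled.

**Method 2** keeps a mention iff Method 1 keeps it *and* a PPI+ive lemma
is spotted in a context sentence; its keep-set is a subset of Method 1's
by construction.

**Method 3 (SVM).** Six features per residue-containing sentence: S_X,
the root-anchored keyword scores of the preceding and following sentences
(same sum as S_X but measured from the tree root, 0 when the neighbour or
its tree is missing), and S_prot ∈ {0,1,2} — neither/one/both partner
names present — for each of the three sentences.  No feature scaling is
applied (the features are already bounded and commensurate;
standardisation is available).  The classifier is an SVC with RBF kernel,
γ = 16, C = 1 (the published configuration reports only the kernel and γ;
C = 1 is the package default), trained on a label-stratified seeded 50/50
split; the held-out half provides precision/recall/accuracy/F, with 0/0
ratios reported as undefined rather than 0.  Sentence labels follow the
convention that a sentence is positive iff it contains at least one
interface residue.

## Evaluation

Per complex, P_TM = Σᵢ Nᵢ_int / Σᵢ (Nᵢ_int + Nᵢ_non) over the abstracts
with at least one retained mention; abstracts whose mentions were all
purged are excluded, and a complex with no contributing abstract has
undefined P_TM and leaves the distribution.  Algorithms are compared by
ΔN(P_TM) = N_X1(P_TM) − N_X2(P_TM).  N(0) and N(1) are **exact-endpoint
counts** (P_TM equal to 0 or 1 within 1e-9), matching their reading as
"all false positives" / "all true positives"; histogram plots use ten
right-closed bins.  Aggregate statistics are L_tot (complexes with ≥ 1
retained-residue abstract), L_int (≥ 1 interface residue found),
coverage = L_tot/total, success = L_int/total, accuracy = L_int/L_tot.

## Constraints and docking

Basic confidence: f(R) = min(10, Σ aᵢ), aᵢ = 2 for AND-abstracts, 1 for
OR-only.  NLP re-ranking: 10 if some AND-abstract mentioning R passes the
NLP filter; 8 if R appears in an AND-abstract; 6 if some OR-abstract
passes; otherwise max(5, number of abstracts), **capped at 10** — the cap
is this package's reading of "the range is preserved between 1 and 10",
since without it a heavily cited residue could outrank AND+NLP evidence.
"Passes NLP" means the abstract contains a mention of R that survives the
configured advanced filter (Method 3 by default).  The top five residues
per protein are selected, ties broken deterministically: AND-derived
before OR-derived, more supporting abstracts first, then lower residue
number.

Reference constraints are the three interface residue pairs with the
smallest Cα–Cα distances, each side emitted at f = 10; they bound what any
text-derived constraint set could achieve.  Poses are rescored by the sum
of f over constrained residues at the pose's predicted interface (the same
6 Å heavy-atom rule), sorted descending with the raw docking order as the
stable tie-break — the constraint score is the primary key because the
magnitude of the original scan's internal weighting is not documented.
Constraint residue numbers must be expressed in the numbering of the
models handed to the rescorer (the unbound ligand, typically), using the
unbound↔bound map.

i-RMSD: the unbound ligand (the smaller partner) is least-squares
superimposed on the bound ligand over all mapped Cα atoms; that placement
is the reference.  A pose's i-RMSD is the Cα RMSD over bound-interface
residues between the posed and reference placements, with no further
fitting (the receptor frame is common).  Fewer than three interface Cα
correspondences is an error.  Success: ≥ 1 pose with i-RMSD ≤ 5 Å
(non-strict) in the top 10.

## Synthetic data: what it emulates, and what it does not

The corpus generator plants the statistical signal the filters exploit:
interface mentions are placed grammatically near PPI+ive keywords
(probability 0.9 by default), non-interface mentions near PPI-ive keywords
(0.8), context sentences and partner-name insertions follow the same
asymmetry (0.9/0.8 and 0.8/0.5), abstracts are AND-retrieved with
probability 0.3, and half of all mentions are interface.  Sentences come
from a fixed catalogue of template skeletons whose bracketed parses are
emitted alongside; near-keyword skeletons attach the keyword and residue
leaves directly under a shared constituent at edge distance 2 or 3, so a
single planted keyword yields S_X = 1/2 or 1/3 — decisively above the
0.25 threshold — while real parser output would hang tokens under
part-of-speech nodes and shift these distances.  Generation is a pure
function of the recipe and seed.

Toy complexes are Cα + pseudo-Cβ traces along parallel lines with exactly
`n_contacts` residue pairs inside 6 Å (contact Cα–Cα distances 5.0–5.2 Å,
staggered so the reference-pair ranking is unambiguous); unbound forms add
isotropic Gaussian coordinate noise (σ = 0.5 Å default), numbering offsets
and different chain IDs.  Pose sets mix small perturbations of the
reference placement with large random transforms scattered 15–45 Å around
the receptor, recording each pose's true i-RMSD.

Passing tests on these data show that the implementation recovers planted
signal under the stated noise; they do not show that abstracts of real
papers carry that signal at those rates, that the template grammar spans
real syntactic variety, or that the fixture similarity lexicon matches
WordNet behaviour.  The benchmark sizes used by the test-suite and the
acceptance script — 200 complexes × 3 abstracts for the corpus
comparisons, five 500-pose sets for docking — were chosen as the smallest
sizes at which the endpoint counts ΔN(0)/ΔN(1) are comfortably away from
zero.

## Numerical and interface choices

- Strict inequalities at every similarity and S_X threshold.
- Alternate locations resolve to the highest-occupancy conformer, first
  wins on ties; only the first model of multi-model PDB files is read;
  hydrogens are ignored in all distance work.
- Kabsch superposition via SVD with a determinant guard against
  reflections; ≥ 3 points required.
- MEDLINE-format input carries no query provenance and defaults to OR,
  the permissive class the advanced filters operate on.
- The pipeline logs one decision row per mention (stage + rule), so
  retained ∪ dropped always equals extracted; TSV outputs carry a config
  hash and seed stamp in a header comment (the fixed plain-corpus format
  itself does not).
- CLI exit codes: 0 success, 2 configuration error, 3 data error.
- The mining/filtering/constraint stages are also importable as library
  functions; the `sitemine` console script is a thin layer over
  `sitemine.pipeline`.

## Known limitations

- No live PubMed retrieval is included; ingestion is file-based (plain
  block format or MEDLINE fields).  Excluding a complex's original
  structure publication is supported by PMID list, not by parsing PDB
  headers.
- No constituency parser is bundled; without sidecar trees the tree-based
  filters abstain.
- The 1-letter mention rule trades precision for recall; corpora heavy in
  gene/strain identifiers should disable it.
- mmCIF, hetero-ligand handling and quaternary-assembly generation are out
  of scope; docking itself (the rigid-body scan) is external — this
  package only generates constraints, rescores pose lists and evaluates
  them.
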