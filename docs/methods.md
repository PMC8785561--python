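# Methods

## Conservation scoring

A column's conservation is the Jensen–Shannon divergence between its
amino-acid distribution and the BLOSUM62 background (the marginal
frequencies of the BLOSUM62 substitution table, embedded as constants
and renormalized to sum to 1). With base-2 logarithms and mixing weight
λ = 0.5 the score is symmetric and bounded in [0, 1], which is why the
downstream thresholds (0.4 / 0.5 / 0.7) can be read as absolute levels.

Defaults, all overridable through `jsd_track` keywords:

| parameter       | default | meaning |
|-----------------|---------|---------|
| `lam`           | 0.5     | JSD mixing weight |
| `window`        | 3       | columns on each side pooled for smoothing |
| `window_weight` | 0.5     | weight of the neighbourhood mean |
| `pseudocount`   | 1e-7    | added per amino acid before renormalizing |
| `gap_penalty`   | on      | multiply by (1 − gap fraction) |
| `use_weights`   | on      | Henikoff position-based sequence weights |

These are the published defaults of the JSD conservation-scoring
recipe this implements; whether the original analyses applied
weighting and windowing is not recorded anywhere we could verify, so
both are explicit toggles. The window excludes the focal column and
truncates at alignment edges (a single-column alignment keeps its raw
score); this choice changes boundary scores and is therefore stated.
'X' residues are excluded from column distributions but are not counted
as gaps — unknowns should neither inflate conservation nor trigger the
gap penalty. Pairwise identity uses the alistat/esl-alipid convention:
identical columns over columns where both sequences are non-gap, with
zero-co-aligned pairs excluded from the mean and flagged.

## Interface detection

The cited interface tools (PIC/HBPLUS/NUCPLOT class of programs) do not
print their numeric criteria, so explicit hydrogen-free distance
criteria are fixed here and exposed in `ContactParams`: generic 5.0 Å
between any inter-chain heavy atoms; hydrogen bond 3.5 Å between
donor-class and acceptor-class atoms (no angle term — cryo-EM models
lack hydrogens); ionic 6.0 Å between Asp/Glu carboxylate oxygens and
Lys/Arg/His side-chain nitrogens, or a protein charged group vs an RNA
phosphate; hydrophobic 5.0 Å between apolar side-chain carbons. An
interface residue is any residue with ≥1 qualifying contact of any
type. Contact search uses a KD-tree but is tested for exact equality
against exhaustive all-pairs enumeration.

Unions across structures require an explicit residue-numbering map
(structure residue → reference position); there is no automatic
superposition, so cross-species unions are deterministic and auditable.
Unmappable residues are reported, never dropped. The %-at-interface
denominator defaults to residues resolved in the structure (the
alternative, full sequence length, is a parameter) because the original
percentages' denominator is not stated.

## SASA and core/rim

SASA is computed with an own Shrake–Rupley implementation (Fibonacci
sphere, 960 points/atom by default, probe 1.4 Å, standard van der Waals
radii), validated against the closed form for an isolated atom, a caged
atom, the distant-chain limit, and biotite's independent
implementation. rSASA normalizes per-residue SASA by Gly-X-Gly
theoretical maxima (Tien et al. 2013 values, embedded). Core/rim
thresholds: published descriptions of the scheme give "core ≤ 0.7%"
next to "rim between 7 and 10%", which is internally inconsistent; we
read 0.7% as a typo for 7% and default to core ≤ 7%, rim (7, 10]%, both
thresholds parameters. A core residue must additionally be
surface-exposed in the unbound component (rSASA > rim threshold).

## Phylogenetic profiling

Profiles are raw 0/1 columns (no normalization — none is documented for
the original). Distances are 1 − Pearson correlation; hierarchical
clustering is scipy's average linkage, with components sorted
lexicographically first so ties break deterministically. A component
present in every species makes the correlation undefined; this fails
loudly with a pointer to the Jaccard-distance fallback flag rather than
propagating NaNs into the linkage. Flat clusters are cut at a
user-supplied k (or height) — the original read groups off a dendrogram
by eye, and inventing a model-selection step would add an assumption
the analysis does not have. Species-row clustering is display-only and
omitted; the inferential claim is about component groupings. The
dendrogram serializes to newick with branch length = parent merge
height − child merge height, so leaf depth equals the root height.

## Motif scanning

The five proline-rich motifs are literal wildcard strings, so scanning
is exact position-wise matching (the probabilistic MAST search used
originally can only deviate from this by its own approximations). All
overlapping occurrences are reported; classification needs only ≥1 hit
in the scanned region. The scanned region is the annotated C-terminal
tail from a required region table (domain assignment is out of scope);
a full-sequence mode exists as a flag. Disorder is an optional external
annotation, never predicted. Sequences without a region row or with an
out-of-bounds region are counted as "unscanned" so class counts always
reconcile with the input count.

## Reports

Interface-conservation cells are means of windowed JSD over mapped
owner-side interface residues (the windowed score is the module-wide
default; raw-score output is also emitted). An empty interface is
undefined (NaN), not 0. "Above threshold" in site reports is strict,
matching the wording it implements; threshold and strictness are
parameters. The overlapping vs non-overlapping comparison uses a
two-sided Mann–Whitney U (exact null for group sizes ≤ 20, normal
approximation with tie correction otherwise) — chosen as the
assumption-light default since no test is named in the original
description; the choice is recorded in run metadata. Per-taxon residue
compositions reuse the conservation-scoring sequence weights for
consistency (unweighted mode available). The critical-pair rule is
exactly "(one side JSD > 0.5) and (other ≥ 0.4) and in contact".

## Synthetic data

The generators emulate the *shape* of the real inputs, not their
evolutionary process:

* `simulate_msa` — conserved columns put ≥95% mass on one residue (the
  dominant count is fixed at ⌈0.95·n⌉ so the planted signal is
  guaranteed per column, with the 5% substitution mass spread uniformly
  over the other 19 residues); variable columns are i.i.d. BLOSUM62
  background; gaps are i.i.d. per cell (rate 0.05 by default) in
  variable columns only. No tree-based substitution model, no indel
  blocks, no rate variation — so tests show the scorer separates
  planted signal from background, not that it handles phylogenetic
  autocorrelation.
* `simulate_complex` — single-atom (optionally two-atom) pseudo-residues
  on a 28 Å grid with ≥80 Å between chains; each planted contact moves a
  guest residue so a designated atom pair lies at a drawn distance in
  [3.0, 4.9] Å. The construction is verified after placement: planted
  residue pairs are exactly the inter-chain pairs within 5.0 Å and all
  unplanned pairs are > 6.5 Å apart, with bounded retries otherwise.
  The optional side-chain mode (Ser/Asp/Lys/Leu menu) exercises the
  hbond/ionic/hydrophobic classifiers.
* `simulate_profiles` — one Bernoulli presence draw per (species,
  module) shared by all module members (default rate 0.7; the study
  drivers use 0.8/0.6 for the two modules), then independent bit flips
  at 5% — chosen as a realistic detection-noise level for homolog
  searches; no phylogenetic correlation between species.
* `simulate_motif_sequences` — uniform background re-drawn until it is
  motif-free, then one motif instance per sequence planted in the
  C-terminal third, wildcards instantiated from non-proline residues;
  each sequence is re-scanned and accepted only if the hit set equals
  the planted set exactly.

Study sizes in the analysis drivers (40-sequence alignments of 100–260
columns, 4-chain toy complexes, 200 species, 120 homolog tails) are the
package's choice of a desk-scale study that exercises every code path;
the real SF3b datasets are one to two orders of magnitude larger.

## Verification battery

`scripts/acceptance.py` recomputes, from scratch at each run: max
deviation of the JSD track from a plain-loop oracle (100 random
alignments ≤10×20); min AUC for planted conserved columns (10 seeds of
50×200/30 planted/5% gaps); contact mismatches vs exhaustive search (50
toy complexes); planted-module recovery (20 seeds at 5% noise, k=2);
motif-scanner mismatches vs an exhaustive matcher (1000 sequences) plus
planted-hit recovery (100 sequences); SASA closed-form %-error and the
distant-chain bound=unbound limit; and critical-pair rule mismatches on
the {0, 0.05, …, 1}² grid × contact/no-contact. All oracles live in
`tests/oracles.py` and share no code with the pipeline paths they
check.

## Known limitations

* No tree-aware conservation (rate4site-style) or dN/dS — sequence-level
  JSD only.
* Hydrogen-bond detection has no geometric angle term; subtype calls on
  real structures are approximations of the donor/acceptor chemistry.
* Atom-role tables cover the 20 standard residues and standard RNA
  nucleotides; exotic residues fall back to generic contacts and a mean
  reference SASA (with a warning).
* Cross-structure unions are only as good as the supplied numbering
  maps; no sequence/structure alignment is computed internally.
* Correlation-distance profiling treats species as independent samples;
  shared ancestry inflates apparent co-occurrence.
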