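# sf3bcons

Conservation analysis of multi-protein complexes, built around a case
study of the spliceosomal SF3b complex — the seven-protein (six in
yeast) U2 snRNP subcomplex that clamps the pre-mRNA branch-point region
during spliceosome assembly.

The package is for computational biologists asking how conservation is
distributed across a complex: which components are conserved, whether
residues at inter-component interfaces are more conserved than the rest,
whether components co-occur across species in a way that betrays
subcomplexes, and how annotated functional sites (disease mutations,
drug-binding residues, short linear motifs) behave across lineages.

## What it computes

**Per-column conservation (Jensen–Shannon divergence).** For a column
*c* of a protein alignment with amino-acid distribution *p_c* and the
BLOSUM62 background distribution *q*,

    JSD(p_c, q) = ½ KL(p_c ‖ r) + ½ KL(q ‖ r),   r = ½ (p_c + q)

with base-2 logarithms, so scores lie in [0, 1]; higher means more
conserved. Column distributions use position-based (Henikoff) sequence
weights and a small pseudocount; gapped columns are penalized by
(1 − gap fraction), and scores are smoothed over a ±3-column window.

**Interfaces.** Multi-chain structures (PDB/mmCIF via gemmi) are mapped
to named components; an interface residue is any residue with at least
one inter-chain heavy-atom contact within 5.0 Å (with hydrogen-bond,
ionic and hydrophobic subtypes under their own hydrogen-free distance
criteria). Interface sets are unioned across structures from different
species/assembly states through explicit residue-numbering maps.
Interface residues are split into core/rim by relative solvent
accessibility (own Shrake–Rupley SASA against Gly-X-Gly maxima):
core residues are surface-exposed alone but ≤7% rSASA in the complex.

**Phylogenetic profiles.** Species × component presence/absence
matrices are clustered with the correlation distance (1 − Pearson r)
and average linkage (UPGMA); correlated profiles flag putative
subcomplexes.

**Motifs.** Exact wildcard scanning of C-terminal tails for the five
proline-rich motifs PPRxxP, PPPPP, PxPPxR, PPLP, PPxY, classifying
homologs as human-like (motif or annotated disorder) vs yeast-like.

**Reports.** Per-protein summaries, the owner × partner
interface-conservation matrix, overlapping (bifurcated) vs
single-partner interface comparison (Mann–Whitney U), two-sided
conserved "critical" contact pairs (one side JSD > 0.5, other ≥ 0.4),
and annotated-site conservation readouts.

A seeded synthetic-data module generates all inputs with known ground
truth (planted conserved columns, planted contacts, planted
co-occurrence modules, planted motifs), so the whole pipeline is
testable end to end without downloads.

## Worked example

The analysis is a sequence of numbered drivers; each prints what it
found and writes its tables under `results/`:

```sh
python analysis/01_simulate_inputs.py   # seeded study inputs + truth sidecars
python analysis/02_conservation.py      # JSD tracks and identity per component
python analysis/03_interfaces.py        # contacts, interfaces, core/rim
python analysis/04_profiles.py          # profile clustering
python analysis/05_motifs.py            # proline-rich motif screen
python analysis/06_report.py            # joined summary reports
```

Output of `02_conservation.py` on the default seed:

```
SF3b1    mean JSD 0.269 | identity  26.8% | planted conserved cols score 0.549 vs variable 0.186
SF3b14b  mean JSD 0.369 | identity  39.2% | planted conserved cols score 0.578 vs variable 0.243
...
planted conserved columns score above variable ones in every component: True
```

i.e. components generated with more planted conserved columns (the
"core" components SF3b14b/SF3b5) come out with higher mean JSD and
identity, and within every alignment the planted conserved columns
score far above the background columns. `04_profiles.py` reports

```
flat clusters (k=2):
  cluster 1: SF3b14b, SF3b5, SF3b6
  cluster 2: SF3b1, SF3b2, SF3b3, SF3b4
planted modules recovered exactly: True
```

— the two planted co-occurrence modules are recovered from the noisy
presence/absence matrix — and `05_motifs.py` reports the planted
64%/36% human-like vs yeast-like split with every planted motif hit
recovered exactly.

## Layout

```
src/sf3bcons/      library: alignment, structure, profiles, motifs,
                   report, synthetic
analysis/          numbered narrative drivers (01..06)
tests/             pytest suite + independent brute-force oracles
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
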