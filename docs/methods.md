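# Methods

This note records the models implemented, the defaults chosen where the
underlying analysis protocol left choices open, and what the synthetic
benchmark does and does not demonstrate.

## Pairwise alignment and identities

Global and local alignments use the three-state Gotoh affine-gap
formulation via Biopython's `PairwiseAligner` (C implementation), scored
with BLOSUM62, gap-open 10 and gap-extend 0.5; a gap of length L costs
`open + (L−1)·extend`. The canonical alignment reported is the first in
the aligner's deterministic enumeration order, which makes reruns
byte-identical. Global alignments penalise end gaps by default
(`ScoringScheme(end_gaps=False)` switches to free end gaps, the EMBOSS
needle `endweight` behaviour; the exemplar identity spot checks use free
end gaps since that is what the EMBOSS web defaults apply). Percent
identity defaults to identical columns over alignment length (the EMBOSS
convention); identity over the shorter sequence is an option because
published identity figures do not always state their denominator.

Molecular masses are sums of average (isotope-weighted) residue masses
plus one water (18.0153 Da). `X` residues are rejected unless the mean
residue mass is explicitly enabled. Coordinates are 0-based half-open
internally and 1-based inclusive in every user-facing table.

## Progressive multiple alignment

Guide trees are UPGMA (average linkage) over 1 − shared-3-mer-fraction
distances; inputs are sorted by id first so results are independent of
file order. Profiles are merged bottom-up with an affine Gotoh recursion
over expected sum-of-pairs BLOSUM scores; gaps, once inserted, are never
removed. This is a deterministic desk-scale aligner: the questions asked
of its output (clade groupings, domain-region extraction, logo columns)
are robust to small column-level differences, and no iterative
refinement is attempted. Reference domain boundaries are projected onto
other rows through alignment columns; rows fully gapped across a region
are reported as missing rather than given an empty interval.

## Domain architectures

The domain vocabulary is closed (LisH, CTLH, CRA, RING, SPRY, kelch,
WD40, armadillo, discoidin, other); external InterPro/SMART/Pfam ids map
onto it, unknown ids fall back to `other`. When exactly one of the
LisH/CTLH pair is annotated, the partner is inferred from a fixed
window: 50 aa N-terminal to the CTLH (a LisH is typically 35 aa) or
70 aa C-terminal to the LisH (a CTLH is typically 50 aa). Windows are
clipped at sequence bounds and truncated at neighbouring annotations
rather than rejected — the protocol applies the windows uniformly
without stating edge handling, and clipping keeps the operation
idempotent; collapsed windows add nothing and are flagged. The built-in
PSSM scanner uses a uniform 1/20 background with pseudocount 0.5 per
cell and reports greedily non-overlapping hits, best first.

Architecture matching is an ordered-subsequence test: a candidate
matches a component template when at least two of the template's domain
types occur in template order; extra domains are ignored, so the match
is monotone under insertions. The two-domain lower limit deliberately
excludes single-domain candidates such as lone RING proteins.

## Orthology

Candidates are searched against the component reference set (two
exemplars per component, drawn from different supergroups) with exact
Smith–Waterman; raw scores become bit scores via the Karlin–Altschul
transform with the standard gapped-BLOSUM62 constants λ = 0.267,
K = 0.041, and e-values via E = m·n·2^(−bits) with m the query length
and n the database residue count. The default cutoff is 1e-5, with
stricter presets 1e-15 and 1e-30 exposed for profile-style and
translated-style search regimes. A candidate is an orthologue of the
component of its best reference hit when its architecture matches and it
forms a reciprocal best hit with that reference within its own proteome;
family members failing only reciprocity (extra copies) are paralogues.
Clade placement and length similarity (default ±40% of an exemplar
length — "similar length" is not quantified anywhere authoritative, so
the threshold is configuration, not truth) are recorded as soft criteria
and can be made vetoing; soft is the default because genuinely divergent
orthologues would otherwise be discarded.

## Sequence logos

Column frequencies are taken over non-gap residues with a per-column
effective count (`count_as_missing` instead keeps the row count,
deflating ragged columns). Information content is the Schneider–Stephens
measure, R_i = log2 20 − (H_i + e_n) with e_n = 19/(2 ln2·n), clamped to
[0, log2 20]; the small-sample correction is on by default and letter
heights are f(a,i)·R_i, so heights sum to R_i per column. Conserved
positions are columns whose top letter reaches a bit threshold (default
2.0, the threshold used for mapping charged residues onto structures),
annotated with a fixed residue-class scheme (basic K/R/H, acidic D/E,
amide N/Q, polar S/T/C/G/Y, hydrophobic A/V/L/I/P/W/F/M). No redundancy
weighting is applied; an explicit choice, since the upstream protocol is
silent on it. Logo comparison uses per-column Jensen–Shannon divergence
in bits (symmetric, zero iff equal) summarised by the mean — a
formalisation of what is otherwise a visual comparison.

## Variant RING domains

The matcher searches for C-x2-C-X(9–39)-C-x(1–3)-H-x(2–3)-C-x2-C-
x(4–48)-C-x2-C, leftmost match with shortest spacers (lazy quantifiers);
a disambiguation rule is needed because the variable spacers admit many
parses. Chosen slots may be relaxed to S/T/G to admit known functional
variants, and the search can be restricted to the final 120 residues,
where elongated MAEA-like RING-like regions sit. Classification is a
pure function of the eight slot residues: all-canonical → RING-HC (two
zinc ions); ≥2 S/T substitutions in one site with the other intact →
RING-S/T; the same with G → RING-G; both substitution types → mixed; a
site with fewer than three identifiable (C/H/S/T/G) residues →
degenerate. The predicted zinc count is the number of sites whose four
slots are all C/H, which makes it monotone non-increasing under slot
degradation. Family-level calls read the top logo residue per slot,
using '?' below 1 bit.

## Trees, profiles and Dollo parsimony

Protein distances are computed over pairwise non-gap columns as p,
Poisson (−ln(1−p)) or Kimura (−ln(1 − p − 0.2p²)) distances.
Neighbor-joining uses the Saitou–Nei Q-criterion with ties broken by
taxon label; negative branch lengths are clamped to zero with the
deficit moved to the sister edge. NJ with distance-based bootstrap
(columns resampled with replacement; support = % of replicate trees
containing each bipartition) deliberately replaces full ML/Bayesian
inference: the questions asked here — which families pair at depth,
which clades are monophyletic — are topology-level and answerable at
desk scale, and this substitution is a central design decision of the
package. Monophyly is evaluated on unrooted trees via bipartitions, with
intruders listed from the smallest containing side; an outgroup-rooting
helper is provided.

Presence/absence is scored per species × component from orthologue
verdicts only (paralogue counts do not affect presence). Dollo
parsimony places the single gain at the MRCA of the present species and
one loss on the stem of each maximal present-free subtree below it; this
is the minimum over all feasible single-gain placements (verified
against exhaustive enumeration in the tests).

## Synthetic benchmark: what it emulates

The generator produces the study conditions the analysis assumes:

- a rooted, ultrametric species tree whose labelled supergroups are
  clades (default 8 species in 4 supergroups; root height 0.25 expected
  substitutions/site, inside the divergence regime where reciprocal
  best hits are reliable);
- one gene family per component evolving along it, with Poisson
  duplication/loss (defaults 0 — most real species carry single copies;
  plant-like duplication scenarios raise λ per component);
- domain-block sequences laid out per component template, joined by
  fixed-length linkers evolving 3× faster, so that architecture and
  domain sequence, not linker similarity, drive orthology;
- 20% of domain columns invariant, plus planted variant-RING slot
  residues (S/T-substituted S1 for the Rmnd5-like family; mixed S and G
  for the MAEA-like family) with a conserved proline after slot 7;
- shared LisH+CTLH ancestors for the TWA1/RanBPM and Rmnd5/MAEA pairs
  (within-pair divergence 0.3, between-pair 0.8 substitutions/site), so
  the deep pairing is a planted truth;
- a muskelin-like component restricted to the opisthokont supergroup —
  a post-LECA origin by construction;
- substitutions drawn from a fixed BLOSUM62-derived exchangeability
  table, P(b|a) ∝ exp(B62[a,b]/3), b ≠ a.

All randomness flows from one seed through numbered generator streams
(stream 0: species tree; 10+i: family i; 100: annotation withholding),
so stages are independently reproducible and re-runs are byte-identical.

What it does **not** emulate: indels inside domains (domain columns are
indel-free so truth coordinates stay exact), length variation of
linkers, compositional bias, fragmentary gene models, or database
contamination. Passing benchmarks therefore demonstrate the pipeline's
correctness under its stated model, not robustness to the full
messiness of real proteomes; the exemplar spot checks on the named
RefSeq sequences (network-dependent) are the bridge to real data.

## Problem sizes

The default test benchmark uses 8 species × 8 components (58 genes);
the acceptance script uses 12 species (≈ 90 genes) with 100 bootstrap
replicates. Both complete in well under a minute per run on one CPU;
these sizes were chosen as the smallest at which every structural
question (supergroup clades, deep pairing, restricted-component gain)
is non-trivially posed.

## Known limitations

- NJ + distance bootstrap, not ML/Bayesian inference; support values are
  not comparable to PhyML bootstrap proportions on real data.
- The progressive aligner has no iterative refinement; very divergent
  rows can misalign, which is why logo truth checks are restricted to
  the indel-free synthetic regime.
- Secondary-structure-informed domain boundary curation is out of
  scope; boundaries come from annotations or the fixed windows only.
- The e-value model is a documented surrogate for a full search engine's
  statistics; absolute e-values are comparable within a run, not to
  BLAST output.
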