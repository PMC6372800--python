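# Methods

## Model and procedure

TraA-mediated recognition is modelled as a pairwise compatibility relation
over alleles, evaluated on their variable domains (VDs) and then closed into
a partition. The pipeline runs in five stages.

**1. Registry and screening.** Alleles are protein sequences with IDs of the
form `Prefix_StrainID`; the prefix vocabulary maps to species and suborder
(Cystobacterineae / Sorangiineae / Nannocystineae), with unparseable prefixes
accepted as `unknown` rather than rejected. Deduplication is sequence-level:
byte-identical sequences collapse to the lexicographically first ID, because
allele uniqueness is a statement about the protein, not its label. The
ortholog screen keeps a homology hit iff `evalue < 1e-100` **and**
`query coverage > 0.80` (both strict, matching how the cutoffs are stated)
and, by default, the *traAB* operon partner is present at the subject locus.
Coverage supplied as a percentage (values in (1, 100]) is rescaled to a
fraction with a logged warning. Reason codes name the first failing
criterion in the order evalue, coverage, partner.

**2. Domain annotation.** All landmark mapping goes through one global
aligner: Needleman–Wunsch–Gotoh, BLOSUM62, affine gaps with open 10 and
extend 0.5, where a gap run of length *k* costs `open + (k−1)·extend` (the
first gapped column pays the opening; this matches the convention of
Biopython's `PairwiseAligner` with `open_gap_score=-10, extend_gap_score=-0.5`,
against which the implementation is cross-checked in the tests). Traceback
ties are broken in a fixed order — substitution column, then gap in the
first sequence, then gap in the second — so alignments are deterministic.
The VD of an allele is the set of its residues aligned within reference
positions 62–259 (1-based inclusive, DK1622 coordinates): border columns
where the reference is gapped are trimmed inward, insertions internal to the
span are kept. Extracting the reference against itself returns exactly
residues 62–259. The switch residue is the allele character aligned opposite
position 205 of the switch reference (Mf(HW-1) numbering; the VD reference
and the switch reference are independent arguments and default to the same
record); a gap opposite the site yields `unmapped`. The SCNCCP scan is an
exact substring search. Cys-rich repeats are annotated by a greedy
left-to-right scan: each ~20-residue window containing ≥ 2 cysteines becomes
a repeat C1..Cn; window length and cysteine minimum are parameters because
repeat boundaries are not formally defined anywhere — the annotation is a
descriptive aid, not an input to grouping.

**3. Pairwise comparison.** Percent identity is
`100 × identical columns / alignment columns` of the global VD alignment;
gap columns count in the denominator. Alternative denominators ("shorter",
"mean") are available for sensitivity checks but are not the default: with
VDs pre-trimmed to homologous spans, alignment-length identity keeps the
no-indel criterion independent of the denominator choice. The compatibility
predicate holds iff identity ≥ 90.0 (inclusive), the alignment has zero gap
columns, and the switch residues are identical. An optional equivalence
class (e.g. {A, S}, motivated by S205 behaving like A205 in stimulation
assays) can relax the switch test but is off by default because the
prediction rule as stated demands identical residues. Pairs involving an
unmapped switch are never compatible (fail-closed). The threshold 90% is a
conservative value between the observed within-group minimum (95%) and
between-group maximum (85%).

**4. Grouping.** Predicted groups are connected components of the graph
whose edges are compatible pairs (single linkage). Compatibility behaves as
an equivalence relation on real data; rather than imposing cliques, the
implementation reports every non-transitive triple (a~b, b~c, a≁c) inside a
component as a diagnostic and leaves the component whole. Labels are A, B,
…, Z then numeric, assigned by each component's smallest member ID; an
optional label map pins experimentally characterised alleles to their
published letters. Experimental grouping reads a square donor × recipient
outcome table; a pair is linked when stimulation is positive in at least one
orientation (configurably both), untested cells are treated as negative and
logged, and asymmetric positives are reported. Stimulation efficacy is
`d_allele / d_control` (the control is the DK1622 self-mix on the same
plate); categories are wild-type (> 0.75), very weak (< 0.05 but nonzero),
none (0), and weak for everything in [0.05, 0.75] — only three band anchors
are stated experimentally, so the weak band is the remainder and its edges
are parameters. Partition recovery is scored by exact set-of-sets equality
and the adjusted Rand index (computed via scikit-learn).

**5. Conservation.** Column score = `(1 − gap_fraction) × JSD(P, Q)` with
`JSD = H((P+Q)/2) − (H(P)+H(Q))/2` in bits, which is bounded by 1 and needs
no further normalisation. P is the column's residue distribution after
removing gaps (pseudocount configurable, default 0; `X` is ignored
entirely); Q defaults to uniform over the 20 residues, with the BLOSUM62
marginal frequencies selectable — the original analysis names neither. The
multiplicative gap penalty plus dropping all-gap columns reconciles "gaps
removed" with per-column scoring. No window smoothing is applied by default;
columns above a configurable gap-fraction cutoff can be dropped. The maximal
score for a fully conserved gap-free column against the uniform background
is ≈ 0.855 bits (point-mass limit), the value conserved C-terminal columns
attain in the synthetic profiles.

## Synthetic data: what it emulates, and what it does not

The generator plants a known partition with the identity structure observed
in natural TraA families: within-group VD identity in [95, 100] with no
indels, between-group identity in [45, 85] with an indel in half of the
group pairs (probability 0.5, one indel of 1–4 residues placed away from
the switch site), one switch state per group from {A, P, S, Y} (default:
alternating A and P, the two common states), a 198-residue VD (the length of
the 62–259 span), a 61-residue signal stub so the VD starts at position 62,
and a shared synthetic C-terminal tail of five Cys-rich 20-mers whose fifth
repeat carries SCNCCP exactly once. Defaults generate 5 groups × 4 alleles.

Identity control is by **rejection sampling against the pipeline's own
`vd_identity`**: founders descend from a common ancestor by adaptive random
substitution until every founder pair's measured identity falls inside the
between-group interval (sampling targets the interior of the interval —
a margin of up to 5 points — so that subsequent within-group drift cannot
push cross-group pairs outside it); group members are mutated at mutually
disjoint non-switch positions with per-allele substitution counts of half
the pairwise difference budget, so every within-group pair differs at
exactly the sum of the two counts and lands inside the within-group
interval. All realised pairwise identities are then re-verified, so the
guarantee is exact, not approximate. A single seed fans out to per-stage
substreams (founders, members, stimulation noise); identical parameters and
seed give byte-identical FASTA.

What the generator does **not** emulate: phylogenetic correlation between
groups, codon-level mutation processes, horizontal transfer of VD segments,
alignment ambiguity from long or repeated indels, and annotation noise in
real ortholog calls. Passing recovery tests therefore demonstrates that the
inference is correct when its stated identity assumptions hold — not that
those assumptions hold for any particular natural dataset.

## Numerical choices

- Alignment scores are float64; BLOSUM62 integer scores plus half-unit gap
  extends are exact in floating point, so score comparisons in tests use
  exact or 1e-9 tolerances.
- The aligner's dynamic program is numba-compiled; the first call in a fresh
  environment pays a one-off JIT cost.
- Rejection sampling is bounded (`max_attempts`, default 500) and raises a
  `GenerationError` naming the infeasible constraint rather than looping.
- Degenerate inputs fail loudly: empty sequences, ragged alignments,
  non-square outcome tables, backgrounds not summing to 1 (tol 1e-9),
  asymmetric compatibility matrices.
- Problem sizes in the test suite and acceptance script — 100 recovery
  replicates of 5×4 alleles with 198-residue VDs, 200 oracle pairs of length
  ≤ 12, a 90-allele motif panel — were chosen so each stage is exercised at
  realistic scale while a full run completes in well under a minute per
  stage on one core.

## Design choices where the design was open

- **Pairwise reference alignment, not an MSA**, defines coordinate maps.
  The original trimming used a multiple alignment; pairwise maps are
  deterministic, dependency-free, and sufficient because orthologs share
  the conserved C-terminus. Sensitivity to this choice is the main known
  discrepancy risk for border residues of highly diverged VDs.
- **Connected components, not cliques**, close compatibility into groups;
  diagnostics surface violations instead of hiding them behind a clique
  requirement. No non-transitive case arises under the default synthetic
  conditions (the recovery criterion requires zero diagnostics).
- **The identity denominator** (alignment columns) and the **gap-cost
  convention** are stated explicitly because the original analysis names
  neither; both are parameters or documented constants here.

## Known limitations

- Switch mapping for alleles far below ~45% VD identity can in principle
  land on the wrong column; within the generator's ranges this does not
  occur, but very distant natural orthologs should be checked manually.
- Repeat annotation is heuristic and intended for description, not
  inference.
- The screen approximates the published domain-architecture check with
  motif/repeat annotation; exact reproduction of a curated inclusion set
  from raw hit tables is not guaranteed.
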