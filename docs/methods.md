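# Methods

`cysdom` re-implements, as a tested pipeline, the sequence analysis by which
a duplicated antistasin-like anticoagulant can be identified and
characterized: scanning a protein for the family's cysteine signature,
annotating its domain architecture (including disrupted domains and the
C-terminal motif), computing the physicochemical parameters used to handle
the purified protein, and inferring the duplication history of the
individual domains with a distance-based phylogeny.

## The cysteine signature and the scanner

Antistasin-like domains are recognized not by overall sequence similarity —
which is nearly absent between distant members of the family — but by a
skeleton of nine cysteines with tightly constrained spacings:

```
C-x(4)-C-x(5)-C-x(4,6)-C-x(1)-C-x(4,5)-C-x(3,4)-C-x(9,10)-C-x(2,3)-C-x(1)
```

A signature is an ordered list of inclusive gap ranges between consecutive
skeleton cysteines plus a trailing gap. Two readings of a two-valued spacer
such as `x(4,6)` are possible: the inclusive range [4,6] or the literal set
{4,6}. The scanner uses the range reading, because ranges generalize to
unseen homologs — which is precisely how the signature is useful for
discovery; the literal-set reading can be recovered by writing the pattern
out explicitly.

Matching is exact backtracking over cysteine positions: every skeleton
position anchors a literal `C`, and by default spacers may not contain
cysteines, so the nine-cysteine skeleton is unambiguous (`allow_cys_in_spacer`
relaxes this). `enumerate_matches` returns *all* complete matches, possibly
overlapping, in lexicographic order of their cysteine-position tuples. The
reported match consumes the minimum trailing gap after the last cysteine.

A non-overlapping *architecture* is selected from the enumeration by
interval-scheduling dynamic programming: maximum cardinality, with exact
ties resolved toward the lexicographically leftmost sequence of
`(start, end)` pairs. This makes annotation deterministic and
order-independent.

*Disrupted* domains are maximal prefix matches: chains of at least
`min_prefix` (default 4) correctly spaced skeleton cysteines that cannot be
extended to a complete match, lying wholly outside the complete-domain
intervals. Only N-terminal prefixes are considered — the family's known
disrupted domain conserves the skeleton up to its fifth cysteine and then
diverges — so suffix or internal fragments are out of scope. Overlapping
partial candidates are resolved by the same DP, weighted by prefix length.

The *C-terminal motif* (CTM) is detected as the first `C-X2-C` (X any
non-cysteine) downstream of the last complete domain that is followed by a
proline within a configurable window (default 20 residues) after its second
cysteine. Antistasin itself lacks the CTM; the two anticoagulant paralogs
carry it.

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3
output.

## Protein parameters

Length, cysteine count and fraction are exact counts. Molecular mass is the
sum of average (not monoisotopic) residue masses plus one water, matching
the kilodalton rounding convention of protein reports; Biopython's mass
table is used. The 280 nm molar extinction coefficient is

```
eps_molar = nW*cW + nY*cY + n_cystine*cC
```

with two selectable coefficient sets: Gill & von Hippel (5690/1280/120,
the default) and Pace (5500/1490/125); `n_cystine = floor(nCys/2)` under
the default `all-paired` assumption (appropriate for a disulfide-rich
refolded protein) or 0 under `all-reduced`. The mass extinction coefficient
is `eps_molar / MW(Da)` in (mg/mL)^-1 cm^-1, the scale on which such
coefficients are conventionally printed. `X` residues are rejected by
default; a permissive flag assigns them zero mass and absorbance.

Note that the published coefficient table this computation mirrors is
internally inconsistent: 36,640 M^-1 cm^-1 divided by a mass coefficient of
1.11 implies a ~33 kDa protein, while the stated mass is 28 kDa, and the
coefficient set used is not recorded. The package therefore emits both
conventions and reports the comparison instead of forcing agreement.

## Alignment

Pairwise alignment is classical Needleman–Wunsch/Gotoh with affine gaps:
BLOSUM62, gap open 11, extend 1 (a gap of length L costs 11 + L), with a
fully deterministic traceback (tie order diagonal > up > left). The
alignment method behind the original figures was a GUI platform whose exact
parameters are unstated, so these standard protein defaults are fixed and
configurable. The multiple aligner is deliberately modest — domains of this
family share a fixed skeleton and near-equal lengths — using pairwise
identity distances, UPGMA-style merge order, and profile–profile NW with
sum-of-pairs column scores. The consensus line marks `*` identical columns,
`:` columns within one Clustal strong group, `.` otherwise.

## JTT distances

Evolutionary distances are maximum-likelihood under the Jones–Taylor–
Thornton empirical amino-acid model. The rate matrix is built from the
canonical JTT exchangeabilities and equilibrium frequencies (as distributed
with standard phylogenetics software), scaled to one expected substitution
per site at t = 1, so distances are in substitutions/site. `P(t)` comes
from a one-off symmetric eigendecomposition (the model is reversible). For
two aligned rows the likelihood `sum_columns log[pi(x) P(x->y|t)]` is
maximized over t in [1e-6, 10] by bounded scalar optimization (relative
tolerance 1e-8); gapped columns are pairwise-deleted (complete deletion via
a flag). Saturated pairs are clamped to d_max = 10 with a warning. A
10,000-point (refined) grid search is kept alongside as an independent
cross-check, and an alternative "identity" method inverts the model's
expected-identity curve on the observed p-distance.

## Neighbor-Joining

Classical Saitou–Nei agglomeration on the Q-criterion, exact on additive
matrices. Determinism is guaranteed by breaking Q-ties toward the smallest
(i, j) label-index pair and clamping negative branch lengths to zero (with
a log message). The result is an unrooted tree represented with one
trifurcating root; no rooting is attempted (no outgroup is defined for
these paralogous domains) and no bootstrap is computed. The duplication
grouping is stated as a *bipartition* test — whether some internal edge
splits the five domain leaves into {four-domain D1, D3; two-domain D1}
versus the rest — which is invariant to rooting and drawing order.

## Synthetic families and the reference stand-ins

The generator (`cysdom.synthetic`) produces protein families with exact
ground truth: a signal peptide (plain 20-residue segment, cysteine-free),
tandem domains sampled from the signature (gap lengths uniform over their
ranges, spacer residues uniform over the 19 non-Cys amino acids), linkers
uniform in 5–25 residues, optionally one disrupted domain (the evolved copy
truncated after its 5th skeleton cysteine, tail replaced by cysteine-free
spacer residues of matched length), and a CTM. Domains descend from one
ancestral domain along a configurable duplication tree under the JTT
process; skeleton cysteines are held fixed and substitutions never
introduce cysteines into spacers, so the scanner's ground truth is exact by
construction. Per-branch times come either from a single scalar applied to
every branch or from the Newick branch lengths of the duplication tree.
Everything is driven by one integer seed and is byte-reproducible.

What the generator does *not* emulate: insertions/deletions (domain copies
stay length-aligned), codon-level evolution, rate heterogeneity across
sites, and non-cysteine structural constraints. Passing tests on synthetic
data therefore demonstrate algorithmic correctness under the family's
architectural rules, not performance on arbitrarily divergent real
sequences.

The *reference stand-ins* (`cysdom.standins`) are three fixed synthetic
proteins substituting for the real database entries so the analysis runs
offline. They are engineered to match every published property the
analysis depends on: the four-domain protein has 242 residues, 41
cysteines (17%), ~28 kDa, three complete domains, a disrupted DII
(skeleton conserved through the 5th cysteine), and a CTM; the two-domain
paralog has 139 residues, 22 cysteines, two domains and a CTM; the
antistasin stand-in has two domains and no CTM. Their domain copies differ
by fixed substitution sets that encode the duplication history (shared
substitutions within each duplication group, private ones per domain), so
the NJ tree over the five complete domains reproduces the published
grouping. Tryptophan/tyrosine content is fixed (4/9 and 2/5) so the molar
extinction coefficients land within ~0.2% of the published values under
the default convention. They are synthetic: residue-level identity with
the real proteins is neither available offline nor claimed.

## Benchmarks and problem sizes

The analysis drivers and the reproduction script run, with fixed seeds:
scanner-vs-oracle agreement on 1,000 random sequences (length ≤ 500, Cys
density 5–20%); architecture DP vs exhaustive subsets on 500 cases of ≤ 12
candidate matches; NJ exactness on 100 random additive matrices (4–8 taxa,
branch lengths U[0.1, 2], tolerance 1e-9); JTT ML recovery of t = 0.5 over
100 replicates of 1,000 sites; zero-divergence truth recovery on 200
families; and duplication-grouping recovery on 100 families of four
300-site domains at 0.5 substitutions/site per branch. These sizes keep
every experiment at desk scale while leaving the statistical checks
well-powered.

## Known limitations

* Partial-domain detection is prefix-only by design.
* The progressive MSA is adequate for same-skeleton domains; it is not a
  general-purpose aligner.
* Numeric branch lengths of the original published tree are
  figure-embedded and the software that produced them is unstated, so the
  phylogeny is validated by properties (grouping, additivity, oracle
  agreement), not by reproducing those numbers.
* The cDNA/translation path handles mRNA-sense frames 0–2 only.
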