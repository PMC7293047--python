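# Methods

## The dinucleotide step and its twelve parameters

The unit of analysis is the *step*: the near-dinucleotide fragment of an
RNA or DNA single strand running from C5′ of nucleotide *i* to O3′ of
nucleotide *i + 1*.  Its conformation is summarized by twelve geometric
parameters measured over 18 defining atoms:

| parameter | definition | units |
|---|---|---|
| δ1 | C5′(1)–C4′(1)–C3′(1)–O3′(1) | deg |
| ε1 | C4′(1)–C3′(1)–O3′(1)–P(2) | deg |
| ζ1 | C3′(1)–O3′(1)–P(2)–O5′(2) | deg |
| α2 | O3′(1)–P(2)–O5′(2)–C5′(2) | deg |
| β2 | P(2)–O5′(2)–C5′(2)–C4′(2) | deg |
| γ2 | O5′(2)–C5′(2)–C4′(2)–C3′(2) | deg |
| δ2 | C5′(2)–C4′(2)–C3′(2)–O3′(2) | deg |
| χ1, χ2 | O4′–C1′–N1/N9–C2/C4 per nucleotide | deg |
| μ | N1/N9(1)–C1′(1)–C1′(2)–N1/N9(2) pseudo-torsion | deg |
| NN | N1/N9(1)–N1/N9(2) distance | Å |
| C′C′ | C1′(1)–C1′(2) distance | Å |

Torsions follow the IUPAC sign convention (cross-checked numerically
against gemmi and biotite) and are reported on [0, 360), the convention
of the conformer-class literature.  Purine vs pyrimidine is decided by
atom content (N9 + C4 present → purine), never by residue name, so
modified nucleotides with standard atom nomenclature are analyzed
transparently.  Hydrogens are ignored; only model 1 of a multi-model
file is read; alternate locations are resolved to the highest-occupancy
record, ties broken by the lexicographically smallest altloc label.
Consecutive residues form a step only when the O3′–P distance is ≤ 2.5 Å
(covalent P–O bonds are ~1.6 Å; chain breaks are ≥ 3 Å) and all 18
defining atoms are present.

## Classification

A conformer class (NtC) is defined by a circular mean and a spread for
each of the twelve parameters.  Assignment of a step proceeds in two
stages.

**Voting.**  Parameter *i* votes for a class when its deviation (circular
for angles, absolute for distances) is within
`max(3 · spread_i, floor_i)` of the class mean, with floors of 15° for
angles and 0.5 Å for distances.  Classes reaching a quorum of 11 of 12
votes are candidates.  The multiplier, floors and quorum are explicit,
configurable stand-ins: the vote mechanism of the reference protocol is
asserted in the literature but not parameterized there, so conservative
defaults are exposed on `ClassTable`.

**Nearest-reference selection.**  Among candidates, the winner is the
class of the nearest golden-set member (the labelled reference steps),
or the nearest class centroid when no golden set is supplied.  Distances
use a circularity-aware Euclidean metric over the twelve parameters in
which NN and C′C′ are multiplied by 32 °/Å, placing them on the scale of
the torsions.  Steps with no candidate class are NANT (CANA code NAN);
their diagnostics — nearest class, distance, confal, torsion rmsd — are
still populated against the geometrically nearest class.

**Confal.**  Each parameter scores `100 · exp(−dev² / (2 · spread²))`,
clamped below at 10⁻⁴; the step score is the harmonic mean of the twelve.
The harmonic mean is chosen for its sensitivity to outliers: one gross
parameter crushes the total even when the other eleven are perfect.  The
Gaussian kernel is this package's concrete choice for the per-parameter
form, which the reference protocol does not spell out; the clamp keeps
the harmonic mean defined while preserving that behaviour.  The step
score is clipped into [10⁻⁴, 100] so an exact centroid scores exactly
100 despite floating-point reciprocal sums.

**Rmsd diagnostics.**  Torsion rmsd is the RMS circular difference over
the ten angles against the nearest reference.  Cartesian rmsd between
two coordinate-bearing steps superposes the 18 paired atoms by the
Kabsch algorithm (SVD with determinant correction, proper rotations
only).  When only parameters are available (class centroids, golden
members stored as parameters), an optional diagnostic rebuilds both
steps with the idealized internal-coordinate builder before superposing.

## CANA annotation

The 96 defined classes partition over 14 structural codes — AAA, AAw,
AAu, A-B, B-A, BBB, BBw, B12, BB2, miB, ICL, OPN, SYN, ZZZ — with NAN
reserved for NANT.  The bundled mapping fixes the canonical memberships
(AA00/AA08 → AAA, AA01/AA05 → AAw, BB00/BB01 → BBB, the named OPxx and
ICxx classes → OPN/ICL) and the per-code class counts
(6/5/3/5/8/2/5/2/2/6/7/33/6/6).  ZZ1S is placed under SYN rather than
ZZZ because its name marks a syn-oriented base, the defining feature of
the SYN code; ZZS1/ZZS2 stay under ZZZ as left-handed-helix conformers.
The mapping is user-replaceable data; `validate_partition` checks that a
table and mapping form an orphan-free partition.

## Class discovery

Candidate classes are found by agglomerative hierarchical clustering of
a precomputed circular distance matrix (the same scaled metric as the
classifier), cut at a user-chosen height; average linkage is the default
as the conventional choice for noisy angular data (complete and single
are available).  Clusters with at least 8 members are harvested into
candidates with vector-averaged circular means and circular standard
deviations (√(−2 ln R)); zero-variance spreads are floored at 0.5° /
0.02 Å.  Golden-set growth absorbs, per round, unassigned steps whose
distance to the nearest member of their assigned class is below 1.5×
the class's median intra-class nearest-neighbour distance — a concrete,
configurable reading of "best geometry fit"; growth is monotone and
stops at a fixed point.

## Contingency statistics

Conformer usage across conditions is tested with adjusted standardized
Pearson residuals,
`SPR = (O − E) / √(E (1 − row share)(1 − column share))`, which are
approximately standard normal under independence.  |SPR| > 3 is flagged
significant and |SPR| > 5 stringent, reported side by side.  Because a
row's residuals depend only on its own counts and the table margins,
collapsing other rows into a "rest" row leaves them unchanged — the
property that lets the shipped compact tables reproduce full-table
values.  Row χ² uses columns − 1 degrees of freedom with critical values
from `scipy.stats.chi2.ppf` (at 16 columns: 15 df, 1% critical value
30.58).  The shipped ribosome table's AA03 row computes to SPR 12.2 from
its own printed counts, not the 12.4 printed alongside them; the
recomputed value is reported.

## Motif language

Patterns are hyphen-separated elements (one per step), each a
slash-separated list of exact four-character class names, two-letter
family wildcards (`AAxx`), or `NANT`, e.g. `OP03/OP04-AAxx-AAxx-AA05`.
An optional IUPAC constraint (A, C, G, U/T, R, Y, N; U ≡ T) applies to
the n + 1 bases under an n-step window.  All overlapping matches are
reported; windows never span chain breaks because annotations are
per-chain and skipped steps break contiguity.  The tetraloop scanner
finds N-GNRA-N / N-UNCG-N hexanucleotide windows (five steps) and flags
a window "double-helical" when all five classes are in the AA/AB/BA/BB
families, otherwise "non-trivial".

## Synthetic fixtures

The builder places the 18 defining atoms (plus O4′ for χ) by sequential
internal-coordinate construction (NeRF): each atom from a bond length,
bond angle and torsion, with ideal values from standard nucleic-acid
stereochemistry.  The nine settable torsions (δ1, ε1, ζ1, α2, β2, γ2,
δ2, χ1, χ2) are reproduced exactly (round-trip error < 10⁻¹³ °); μ, NN
and C′C′ emerge from the construction — for A-form torsions the emergent
NN is 4.78 Å and C′C′ 5.21 Å, in the realistic range.  The ribose ring
is not closed: ring closure is irrelevant to the twelve parameters and
would add unverifiable constraints.  In multi-step chains the bridging
torsions are shared (δ1/χ1 of step *i* ≡ δ2/χ2 of step *i − 1*);
supplied values for the shared slots of later steps are ignored.

The parameter sampler draws angles from a wrapped normal around each
circular mean (sd = noise_scale × spread) and distances from a
zero-truncated normal.  The demo class table holds seven classes at
literature-anchored torsion centroids (A-form, B-form, two bridging,
open, intercalation-like, Z-like) with spreads of 8° / 0.25 Å; its
μ/NN/C′C′ centroids are measured from noise-free builds, so a built
centroid scores confal 100 exactly.  Minimum pairwise centroid
separation is 80 scaled degrees, ten times the largest spread.

What the fixtures do *not* emulate: crystallographic noise structure
(coordinate error correlated along the backbone, B-factor dependence),
real class-population imbalance, sequence-conformer correlations, chain
context (the sampler draws steps independently, so consecutive steps of
a sampled chain are not conformationally coupled), and the true
geometry of the 96 published classes — the bundled full table's
geometry columns are deterministic stand-ins (see
`data/ntc_classes_synthetic.csv`), usable for I/O, partition and
plumbing tests but not for assigning real structures.  Passing the
recovery tests therefore shows the protocol is correct and
well-conditioned under its stated assumptions, not that the shipped
geometry matches the reference database.

## Problem sizes and numerical choices

Recovery experiments use 500 samples per class at noise_scale 0.25,
500 uniform-noise steps, 1000 random torsion sets for the round-trip
bound, and 3 × 20 planted members for cluster recovery — sizes at which
the binomial error of a ≥ 99% rate is well below the margin.  Tie-breaks:
altloc ties by label; `fcluster` cut exactly at the cut height is
inclusive; vote ties between candidate classes are resolved by distance.
Degenerate inputs raise typed errors: colinear torsion quadruples,
empty class tables, zero contingency margins, mixed U/T alphabets.
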