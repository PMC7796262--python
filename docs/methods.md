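# Methods

This note documents the models and procedures the package implements, the
choices made where conventions genuinely diverge, and what the synthetic
generators do and do not emulate.

## Leucine-zipper heptad annotation

A bZIP domain is located by the basic-region motif N-x7-R/K (invariant
asparagine, seven arbitrary residues, arginine or lysine). All overlapping
matches are reported; when a protein has several, the family annotator
keeps the left-most hit whose downstream region yields the most complete
heptads — family sequences occasionally contain incidental upstream
matches, and "longest clean zipper wins" is the least surprising policy
for a rule the literature leaves unstated.

The register is pure arithmetic once anchored: the *d* position of heptad
L0 is the first leucine strictly after the R/K; letters a–c precede it
(clipped at R/K+1), e–g follow; heptad k occupies positions
`anchor − 3 + 7k … anchor + 3 + 7k`. Tiling terminates at the first
heptad containing a disruptor residue (that heptad is dropped), at the
sequence end (the trailing heptad is kept truncated, reporting only the
letters that exist), or at `max_heptads` (default 10; plant zippers run
from three heptads to ten or more).

Two deliberate tolerances reflect how real families are curated:

- **Disruptor set = {P}**, configurable. Proline is the only residue the
  structural argument names unambiguously; treating glycine or others as
  disruptors is a judgment call, so they are opt-in rather than default.
- **Weak anchor**: when no leucine exists downstream, the anchor falls
  back to the first of {I, V, M} (aliphatic residues tolerated at *d*)
  and the annotation is flagged `weak_anchor`; with no candidate at all
  the protein is retained with an empty heptad list. Family surveys keep
  members whose heptads lack d-leucines, so absence of a leucine is a
  feature to report, not an error.

The anchor search starts strictly after the R/K; whether leucines inside
the basic region should ever anchor L0 is ambiguous in the source
conventions, and starting after R/K is the conservative reading.

## Dimerization pair rules

In a parallel dimer, position *g* of heptad k contacts position *e* of
heptad k+1 on the partner helix. "Charged" means exactly {D, E, K, R}
(histidine uncharged). Both acidic or both basic → repulsive
(heterodimer-favoring); one of each → attractive (homodimer-favoring);
anything else → incomplete. The g↔e′ index offset (k vs k+1) is exposed
as `ge_offset` because the convention is often left implicit; the default
is k+1.

The a↔a′ table is the minimal closure of the stated rules — homotypic
V/I/R favorable, N↔V hetero-favoring, N↔I destabilizing, two charged
residues destabilizing, everything else neutral. Unlisted combinations
are deliberately *not* extrapolated into an energy model.

Position composition (`position_frequencies`) counts heptads L0–L4 by
default; truncated heptads contribute only the letters they carry, X is
excluded from denominators, and a `complete_only` mode restricts to full
heptads since it is unknowable whether published percentages included
partial ones. Reported percentages round half-up to integers.

## Nei–Gojobori Ka/Ks

The estimator is the original unweighted counting method:

- Sites: for each codon position, the fraction of the three
  single-nucleotide changes that are synonymous; changes creating stop
  codons count as nonsynonymous. S is the average of the two sequences'
  site sums over compared columns; N = 3·(columns) − S.
- Differences: per differing column, synonymous/nonsynonymous step counts
  are averaged over all orderings of the differing positions. Pathways
  passing through stop codons are skipped; if every pathway does, all are
  counted, with stop-involving steps scored nonsynonymous (the original
  description leaves this to the implementer; the choice is switchable
  via `skip_stop_paths`).
- Correction: pS = Sd/S, pN = Nd/N, then Jukes–Cantor
  d = −(3/4)·ln(1 − (4/3)·p). Estimates carry flags: `jc_saturated` when
  an argument is non-positive (distances absent), `ks_zero` when Ks = 0
  (ratio absent), `ok` otherwise. There is no transition/transversion
  weighting — that is the modified method, out of scope.

Codon alignment is protein-guided (translate, global BLOSUM62 alignment
with linear gap −8, thread codons back); terminal stop codons are trimmed
before analysis, internal stops are errors naming the codon. Alignment
scores are configuration, not science — the simulated acceptance data
contains no indels, so they do not affect recovery results.

`ratio_from_table` rounds half-up to two decimals to match tabular
reporting. Duplication typing calls a located pair tandem when it shares
a chromosome and either has ≤ `max_intervening` annotated genes between
the two loci (default 5) or a gap ≤ `max_distance` (default 100 kb);
these thresholds stand in for a collinearity tool's block definition and
are exposed as parameters.

## Gene structure

Intron phase i is the cumulative coding length upstream of intron i
modulo 3, with CDS spans ordered 5′→3′ in transcript orientation. Phases
are computed on CDS only: phase is a reading-frame concept, and UTR
introns have none. Each coding exon is labeled with its flanking phase
pair using virtual phase 0 at the CDS start and end, so terminal exons
receive classes like (0,0) on the same footing as internal ones. Models
whose CDS length is not divisible by three are processed and flagged
`partial` rather than rejected — genome annotations contain partial
models and silent failure is worse than a flagged estimate.

## Promoter cis-elements

Promoters are the 2000 bases immediately 5′ of the TSS in transcript
orientation (reverse-complemented on the minus strand), clipped with a
warning at chromosome edges. Motifs are IUPAC strings; counting slides by
one position so overlapping occurrences all count, scans both strands,
and counts reverse-complement-palindromic patterns (e.g. the G-box
CACGTG) on one strand only to avoid double counting. Only the three
ACGT-core boxes (A-box TACGTA, C-box GACGTC, G-box CACGTG) have sequences
fixed by the bZIP literature; every other entry in the bundled
`cre_motifs.yaml` is this package's transcription of the public PlantCARE
consensus and is explicitly editable configuration.

## Protein properties

Molecular weight sums average-isotope residue masses plus one water
(conventional for whole-protein reporting; monoisotopic masses would be
wrong at this scale). X residues error by default or substitute the mean
residue mass under a flag. The isoelectric point solves Q(pH) = 0 where
Q sums Henderson–Hasselbalch protonation fractions over the termini and
the K, R, H, D, E, C, Y side chains with the EMBOSS pKa constants
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1), by bisection on [0, 14] to 1e-3; Q is strictly decreasing so
the root is unique.

## Expression summaries

Clustering is agglomerative with Euclidean distance and complete linkage
(merge heights are monotone); the scipy implementation provides the
deterministic smallest-index tie-break, and the dendrogram object exposes
merges, leaf order, k-cuts, and a newick export. The DE filter uses
inclusive boundaries (log2FC ≥ 1.2 or ≤ −1.2, padj ≤ 0.05). Expression
banding maps log2 values to low (< 2), moderate (4–6 inclusive), and
high (> 6); the 2–4 range that the named bands leave uncovered is mapped
to an explicit `moderate_low` level, and the overlap of band edges at
exactly 6.0 is resolved to moderate by configuration. Missing values
fail fast. Report assembly writes one TSV/JSON per stage plus a manifest
with config, seed and version — and no timestamps, so reruns are
byte-identical.

## Synthetic generators: what they emulate, and what they do not

All generators draw from one seeded NumPy generator per call; identical
spec and seed give byte-identical output, and each returns ground truth
sufficient to score its stage without re-derivation.

**Zippers.** Proteins are flank + basic region + contiguous a–g heptads
+ terminating proline + flank. Per-position composition defaults are the
family-survey rates (65% L at d; 43%/28% charged at g/e; 30% {N,I,V,M}
at a). Background residues exclude {N, K, R, L, I, V, M, P}, so exactly
one basic-region motif exists and the anchor rule cannot land
off-register; the g/e miss branch additionally excludes D/E so the
planted charged fraction equals its probability. Consequence: leucine
occurs only at *d* positions, so when the L0 heptad lacks a d-leucine
the annotator re-anchors at the first leucine-bearing heptad —
register letters stay correct but heptad indices shift. Full-truth
recovery is therefore asserted on `p_leu_d = 1.0` families, and
composition statistics are measured on the planted truth. Real proteins
are messier in exactly the ways the annotator's configurability covers
(other disruptors, aliphatic anchors, incidental motifs).

**Codon pairs.** A uniform-sense-codon ancestor evolves along two
independent lineages; proposals are uniform single-nucleotide changes
with Poisson intensity `expected_subs_per_codon` *proposals* per codon
per lineage (0.15 by default), stop-creating candidates are rejected,
and acceptance is min(1, ω) for nonsynonymous vs min(1, 1/ω) for
synonymous — the acceptance ratio equals ω for any ω > 0. This is a
proposal/acceptance scheme, not a rate-matrix simulator: it yields exact
realized-event truth for estimator recovery but no transition bias,
codon-usage bias, or indels. Because stop-adjacent nonsynonymous changes
are never accepted while the estimator counts them as nonsynonymous
sites, recovered Ka/Ks runs ~5% below ω — visible in the acceptance
report and well inside the 15% recovery band.

**Gene models.** `phase_pairs` lists the (left,right) class of every exon
but the last; the final exon closes the frame with (last right, 0).
Chained consistency is validated, exon coding lengths are drawn congruent
to the required residue modulo 3, and the gene is embedded with random
introns on either strand. Sequence content is random — phase analysis is
pure coordinate arithmetic and never reads the bases.

**Promoters.** Planted occurrences are concrete instantiations of IUPAC
patterns at non-overlapping positions over a GC-controlled background;
any match not fully contained in planted material is destroyed by point
mutation and rescan (bounded iterations). Truth counts come from the
generator's own sliding-window counter — independent of the scanner's
regex path — over the final sequence, so nested patterns (an ABRE inside
a planted G-box) are reflected honestly rather than hidden.

**Expression.** Each gene group is elevated by `separation` log2 units in
its own sample block over a baseline of 3.0 with Gaussian noise
(σ = 0.5). This plants unambiguous block structure for cluster-recovery
tests; it does not emulate mean-variance coupling, batch effects, or
correlated genes, so passing recovery says the linkage implementation is
correct, not that real tissue panels cluster cleanly.

## Problem sizes and numerical notes

The self-check script and test suite use: 500 planted proteins (3–10
heptads) for register recovery and 1000–2000 heptads for composition
intervals; 100 replicates × 2000 codons per simulated ω ∈ {0.2, 0.5, 1.0};
the full 61×61 sense-codon grid for estimator/oracle equivalence; 30–100
planted gene models and 50–100 planted promoters; 100 random matrices
(n ≤ 6) against a brute-force linkage oracle. These sizes make every
recovery check exact or tightly banded while the whole suite stays
interactive.

Numerical choices: pathway and site quantities are exact rationals
realized in floats (oracle agreement to 1e-12); pI bisection tolerance
1e-3 (checked against a 1e-4 grid to 2e-3); percentage reporting rounds
half-up; dataclasses are frozen and validated at construction.

## Known limitations

- The annotator's multiple-hit policy and the g↔e′ offset default are
  conventions, exposed as parameters rather than claimed as ground truth.
- The NG86 estimator is the unweighted original; sequences with strong
  transition bias will bias Ka/Ks relative to likelihood methods.
- The bundled cis-element patterns beyond the three ACGT-core boxes are
  consensus transcriptions, not a validated motif database.
- Duplication typing classifies *given* pairs; it does not detect
  collinearity blocks.
- Printed-table arithmetic: three of the eleven distinct paralog pairs in
  the bundled table carry ratios that cannot be reproduced from their
  printed two-decimal Ka and Ks by any rounding (they were evidently
  computed before rounding); `ratio_from_table` reproduces 16 of 22 rows
  exactly and the discrepancy is surfaced, not patched.
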