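# Methods

This note documents the models and procedures implemented in
`mapkascade`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Coordinates and gene structure

GFF3 is 1-based closed on disk; everything in memory is 0-based
half-open, converted only at the I/O boundary. Intron phase is the
number of CDS bases upstream of the intron (in transcript orientation)
modulo 3 — the standard convention; an intron interrupting a codon
after k bases has phase k mod 3. Introns inside UTRs are counted in a
transcript's intron total but carry no phase (reported as undefined):
phase is a property of the coding frame. The kinase-domain intron
pattern counts introns whose CDS-coordinate position falls strictly
inside the domain's codon range, so a domain covering the whole CDS
degenerates to the set of coding introns.

## Subfamily classification

Signatures are matched literally over alternation sets with `x` as a
full wildcard. Rule order is specificity order: the 11-position ZIK
pattern, then the 10-position MEKK pattern, then the 9-position Raf
consensus. The ordering matters because a MEKK instance with T at the
alternation and W at the F/W position also satisfies the looser Raf
pattern; conversely a Raf instance almost never satisfies the MEKK
pattern (three additional fixed positions). Positional rules: ZIK
requires the kinase domain to start within 60 residues of the
N-terminus; Raf requires the C-terminal tail after the domain to be at
most 20 % of the protein and the N-terminal regulatory region at least
30 %. A Raf signature without the positional evidence stays
`unclassified` — the Raf consensus also occurs in receptor-like
serine/threonine kinases, so the motif alone is deliberately not
trusted; an explicit exclusion list of known receptor-like kinases is
supported. MW is the sum of average residue masses plus one water; pI
is the bisection root of the Henderson–Hasselbalch net-charge function
with the Bjellqvist pK set (via Bio.SeqUtils.ProtParam). Agreement with
any particular web tool to the last digit is not claimed; the root and
monotonicity properties are what the tests pin down.

## Molecular evolution

Pairwise protein alignment is optimal global Needleman–Wunsch with
affine gaps (BLOSUM62, open −10, extend −0.5 by default) through
Bio.Align.PairwiseAligner. Identity is matches over aligned columns;
coverage is residue-to-residue columns over the longer sequence length.
Tandem-duplicate calls need same chromosome, at most one intervening
gene (configurable — "tightly linked" has no universal definition),
identity > 70 % and coverage > 70 %; union-find clusters linked pairs
and one event is counted per cluster while all qualifying pairs are
listed.

Codon alignment back-translates the protein alignment (every residue
gap becomes one codon gap) after verifying that each CDS translates to
its aligned protein. Ka/Ks is Nei–Gojobori (1986): per-codon synonymous
site fractions (a change creating a stop counts as nonsynonymous),
site totals averaged over both sequences, difference counts averaged
over all minimal mutational pathways for codons differing at 2–3
positions, Jukes–Cantor correction. Two conventions had to be fixed
where the literature varies: pathways passing through a stop codon are
excluded whenever a stop-free pathway exists (the cross-check reference
implementation instead averages over them; the difference is below 0.01
on realistic pairs and is covered by a test), and saturation (p ≥ 3/4)
yields an undefined (NaN) distance with an undefined ratio rather than
an arbitrary cap.

Divergence dating uses T = Ks/(2λ). λ defaults to 6.1×10⁻⁹ synonymous
substitutions/site/year — the single rate consistent with every
(Ks, time) pair in the published duplicate table shipped in
`datasets.py` — and is configurable.

Neighbor joining is the Saitou–Nei algorithm with the Q-criterion;
ties break on the lexicographically smallest label pair so output is
deterministic; the final three nodes join by the three-point formula.
On additive inputs the output tree reproduces the input distances
exactly (patristic check to 1e-8 in tests, cross-read with dendropy).
The default distance for family trees is 1 − fractional identity;
likelihood distances are out of scope.

## Expression screens

All log-ratio screens use log2(x + c) with pseudocount c = 1 by
default (set 0 for data already on a log scale). CV uses the sample
(n−1) standard deviation; its conventional screening bands are < 20 %
(stable) and > 200 % (stage-specific). The fold-change screen excludes
genes whose means in both groups fall below an expression floor
(default 1.0) — low-abundance ratios are noise — and flags
|log2FC| ≥ cutoff (1.0 for development/virus/drought screens, 0.5 for
heat, per the config defaults).

The SAM-style screen is the two-class unpaired d-statistic
d = (x̄_B − x̄_A)/(s + s0) with pooled per-gene standard error s and
s0 = median(s); the full Tusher s0 grid search is deliberately not
implemented. q-values come from label permutations: expected
exceedances over observed at each |d| threshold, made monotone
non-increasing in |d| and capped at 1. Design sizes matter here: with
g genes per group the identity relabeling recurs with probability
1/C(2g, g), which lower-bounds attainable q; recovery tests at
q < 0.01 therefore use six samples per group.

Two-way ANOVA is the closed-form balanced fixed-effects decomposition
with interaction, vectorized across genes and verified against
statsmodels' `anova_lm` to machine precision. Sums of squares that are
mathematically zero emerge as ~1e-30 rounding noise and would turn 0/0
into arbitrary F values, so SS terms below a tolerance (1e-12 of the
gene's total SS plus an absolute term scaled to the squared value
magnitude) are treated as exactly zero; a zero-SS factor then gets
p = 1 and a positive-SS factor over zero error gets p = 0, which is
what makes noiseless planted-truth recovery exact. Benjamini–Hochberg
is the multiple-testing adjustment across genes, per factor.

## Circadian detection

Cosine-template correlation: maximize Pearson r between the series and
cos(2π(t − φ)/P) over a period grid (default {24 h}) and phase grid
(default 1 h step), requiring at least two full periods sampled. The
template family is a single cosine — a reduced HAYSTACK-style model
set — because the screen's only published operating parameter is the
correlation cutoff (0.8). Ties (distinct templates that are identical
at the sampled timepoints) are broken toward the smallest period then
phase after rounding r to 12 decimals, so the argmax is deterministic
rather than float-noise dependent. Constant series have undefined r
and are not cycling. best_r is invariant under positive affine
transforms of the series.

## Promoter scanning

IUPAC consensus matching on both strands; a minus-strand hit is
reported at its plus-strand start coordinate; overlapping hits are all
reported. A sequence `N` matches only motif positions whose allowed
set is all four bases — ambiguous sequence must not create
specific-element hits. The shipped dictionary holds the elements with
printed consensi (HSE, TCA-element, ABRE, motif-IIb, CGTCA-motif,
TGACG-motif, circadian); sp1, G-box, ACE and 3-AF1 have no fixed
consensus here and must be user-supplied. On i.i.d. uniform ACGT
background the expected chance-hit count is exactly
2·(L−k+1)·Πᵢ(|allowed(i)|/4), which the scanner's observed rate must
match within binomial error.

## Mutual-Rank network and cascade prediction

rank_i(j) is j's position in i's partners sorted by descending PCC
(self excluded, 1 = most correlated), ties broken by ascending gene
id; MR is the geometric mean of the two reciprocal ranks. Edges with
MR strictly below the cutoff (default 1500 on genome-scale matrices)
are retained — low MR means strong co-expression. Zero-variance genes
are dropped with a warning before correlation. Triads are all
(MAPKKK, MKK, MPK) triples with MAPKKK–MKK and MKK–MPK edges and one
shared localization; a direct MAPKKK–MPK edge is not required, which
is what lets several cascades share one MKK hub. Plain Pearson is used
throughout; weighted-PCC variants are out of scope.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses
assume, under the study's design: 73 genes split 24/43/6 over
MEKK/Raf/ZIK; heat treatments at 12/22/27 °C for 2/24 h; diurnal
series sampled every 4 h over 48 h (the sampling interval of the real
diurnal compendium is not published; 4 h is the field-typical choice);
2-kb promoters; circadian amplitude-to-noise 5 with additive Gaussian
noise (matching a correlation detector's assumptions); planted log2
effects of 1–2; duplicate pairs at the published tandem Ks values.
Proteins embed exactly one signature instance at a
subfamily-consistent position; CDSs back-translate with uniformly
chosen synonymous codons; intron counts are drawn from the observed
subfamily ranges (MEKK 0–24, Raf 1–16, ZIK 1–8).

The codon mutation model applies Poisson numbers of synonymous (and
optionally nonsynonymous) single-nucleotide codon-neighbor
substitutions, rejecting stops — the simplest process consistent with
NG86's assumptions. In synonymous-only mode a substitution is also
rejected if the resulting codon, read against the *ancestral* codon,
would admit a nonsynonymous mutational pathway (the Leu/Arg/Ser
first-position families), so the NG86 Ka is exactly 0 by construction;
this prunes a rare event class and leaves the Ks calibration within
the tested band (mean NG86 Ks ≈ 0.205 at target 0.2 over 200
replicates of 300 codons).

The ten-cascade co-expression fixture is fully synthetic and
deterministic: gene vectors are linear combinations of orthonormal
zero-mean (Helmert) basis vectors — one per latent factor, one unique
component per gene (weight 0.3), plus a weak common component (0.05
for pathway genes, ~0.2 for background) that strictly separates the
correlation tiers so cross-community rank ties cannot arise from float
noise. The membership map wires the hub topology of the published
cascade table (one chloroplast triad, nine cytoplasmic triads sharing
MKK hubs); with 30 background genes the MR cutoff 10 — a scaled-down
analogue of 1500 on a genome-wide matrix — reproduces exactly ten
colocalized triads, independent of seed.

What the generators do **not** emulate: microarray probe effects,
normalization artifacts, RNA-seq count noise, correlated residual
structure across conditions, paralog cross-hybridization, or real
promoter base composition (backgrounds are i.i.d. uniform so the
chance-hit closed form is exact). Passing tests therefore demonstrate
correctness of the algorithms under their stated assumptions, not
re-derivation of the real-data biology: the real family's counts (86
proteins / 73 genes, subfamily sizes, the 41/7 cycling genes on the
public compendia, the specific published cascades) depend on the real
proteome and the 144-dataset expression collection and are covered
here only by shape-matched fixtures and property tests.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: the 15-row published duplicate table (12
rows with measured expression PCC for the identity–PCC correlation);
200 replicates of 300 codons for the Ks calibration; the 73-gene
default family for classification recovery; the 73-gene, 3-condition
circadian design (noiseless for the shaped 41/7 counts; ten seeds at
amplitude/noise 5 for sensitivity/specificity); 20 seeds × 500
pure-null genes × 1000 permutations for the SAM type-I error; 50
random matrices (n ≤ 30) for the mutual-rank oracle; 25 random
additive trees (n = 4–8) for neighbor joining; 20 two-kb promoters ×
3 planted elements; and the 42-gene ten-cascade fixture. All
randomness derives from `--seed`.

## Known limitations

* NG86 only; no maximum-likelihood (codeml-style) Ka/Ks, no transition
  /transversion weighting.
* SAM is the simplified two-class statistic; no paired or multiclass
  designs, no s0 optimization.
* ANOVA requires a complete balanced design with replicates.
* The circadian detector fits one waveform and a fixed 24-h period by
  default; asymmetric waveforms score conservatively.
* Cascade prediction treats localization labels as exact strings; no
  ontology reconciliation.
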