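# Methods

## Scope and model

`pprscan` models a PPR protein as an ordered N→C array of ~35-residue
repeats, each a hairpin of two antiparallel α-helices that contacts one
RNA nucleotide.  The chain of inference is: motif annotation → per-motif
code residues (positions 5 and 35) → IUPAC consensus word → matrix scan
of a genome with exact p-values → per-gene ranking.  Everything assumes
a 0-order background and independence between motif positions; no
attempt is made to model binding energetics, RNA structure, or
cooperative effects between repeats.

## Structure-based annotation

Helices are assigned from Cα geometry alone, because predicted models
are the expected input and their side-chain/backbone detail is not
reliable enough for hydrogen-bond criteria.  A window starting at
residue *i* is helix-like when

- |d(i, i+2) − 5.45 Å| ≤ 0.55 Å, and
- |d(i, i+3) − 5.10 Å| ≤ 0.50 Å,

the P-SEA-style distance criteria; an ideal helix (rise 1.5 Å/residue,
100°/residue twist, 2.3 Å radius) gives d(i,i+2) = 5.43 Å and
d(i,i+3) = 5.05 Å.  Maximal runs of helix-like windows become segments.
Two smoothing steps make the assignment robust to coordinate noise
without loosening the core criteria: runs whose coverage overlaps or
nearly touches (gap ≤ 2 residues, numbering contiguous) are merged, and
segment ends are extended by hysteresis — a flanking residue joins when
one of its two distances is within tolerance and the other within 1.5×
tolerance.  Segments shorter than 4 residues are dropped.  The helix
axis is the principal component of the segment's Cα cloud, oriented
N→C; for an 11–12 residue helix it deviates from the true axis by ~2°,
well inside the pairing tolerance below.

Hairpins are paired greedily N→C: consecutive helices (i, i+1) form a
motif when the inter-helix loop is ≤ 6 residues, the axis angle is
within 180° ± 50°, the helix centroids are ≤ 12 Å apart, and the total
span is 25–45 residues (bounds chosen to admit repeats shorter than the
35-residue canon).  Greedy left-to-right pairing means each helix joins
at most one motif and numbering from the N-terminus is deterministic;
when a middle helix is compatible with both neighbours the N-terminal
pairing wins.  All thresholds are fields of `HelixGeometryParams`.

Superposition is a standard Kabsch fit: centroids removed, SVD of the
covariance, determinant sign corrected so the rotation is proper, RMSD
is the post-fit residual.  The test suite checks it against Horn's
closed-form quaternion eigenvalue solution, an algebraically
independent route.

## Sequence-based annotation

Each protein window is scored against a width-35 log-odds profile
(half-bits).  The default profile is built from the package's scaffold
consensus with a 0.05 pseudo-frequency on every amino acid against a
uniform composition; a curated externally-derived profile can be
supplied instead (`load_profile`).  Window p-values are exact: the same
discretized-convolution machinery as the nucleotide scanner, over the
20-letter alphabet, with the null drawn from the query protein's own
residue composition (+1 pseudocount per letter) — so a window's p-value
measures surprise within that protein, making the statistic
composition-robust.

Repeat selection maximizes
`Σ (−log10 p − λ) + β · #(adjacent pairs with start spacing 35 ± 6)`
over non-overlapping window subsets by dynamic programming (exactness
verified against subset enumeration).  λ = 2.0 by default — a window
must beat p = 10⁻² to contribute — and β = 1.0 rewards the tandem
arrangement that distinguishes repeat proteins from single-motif
matches.  Ties break toward higher score, then smaller start.

## Recognition code

The code table is data, not code: a TSV of (aa5, aa35) → nucleotide-set
entries, shipped with a default drawn from the combinatorial code
described for plant PPR proteins (e.g. T+N → A, T+D → G, N+D → U,
N+S → C, N+N → pyrimidine) and fully overridable.  Lookup tries the exact pair, then
wildcard patterns most-specific-first, and falls back to N (any
nucleotide) — the same fallback used for motifs whose position 35 falls
past the protein's end.  Position 35 of a motif may legitimately lie in
the linker or the next motif's first helix; it is read from the protein
sequence at start+34 regardless of the motif's own span.  Orientation
is fixed N-terminal motif ↔ 5′ nucleotide, with a `reverse` flag since
the modular convention, not the package, decides this.

## Scanner and exact p-values

The IUPAC word maps to a frequency matrix (allowed bases share the
column mass), then to bits: `s(i,b) = log2((p(b|i) + α·bg(b)) /
((1+α)·bg(b)))` with pseudocount α = 0.1.  Zero-probability bases under
α = 0 clamp to a large negative finite score instead of −∞ so the
matrix stays usable.

Column scores are discretized to integers on a grid of
(max − min)/granularity with granularity 1000; the null pmf of the
total integer score is the position-wise convolution of per-column
distributions under the background, and the survival function gives the
p-value.  Scanning sums the same integer column scores for every
window, so scan scores and null scores live on the identical grid and
DP p-values match exhaustive enumeration over all 4^w words to
round-off (the acceptance script measures ~1e-15).  Windows containing
N score the background-expected column score by default (a `skip`
option drops them).  Reverse-strand windows are scored with the
reverse-complemented matrix — the same integer multiset, hence the same
null — and reported in forward coordinates.

Defaults mirror FIMO where a choice was open: report threshold
p ≤ 1e-4, q-values by Benjamini–Hochberg over all scored windows (both
strands) before thresholding, background estimated from the scanned
genome (+1 pseudocount per base) because mitochondrial genomes are
AT-rich and a uniform background would distort p-values.  Both strands
are scanned for genome input; strand-defined transcript input can use
`strands=forward`.  Note that a strand-asymmetric background breaks the
mirror symmetry of palindromic motifs across strands — that symmetry
holds only for complement-closed backgrounds, which is why the
palindrome test uses the uniform background.

Ranking assigns each hit to every gene feature it overlaps by ≥ 1 bp
(strand-agnostic, since mitochondrial annotation conventions vary);
hits outside all features pool under "intergenic".  A gene's rank
statistic is its best hit p-value — hit counts are reported alongside
but do not affect order — and ties break by gene name.  Top 20 rows by
default.

## Synthetic data: what it emulates, what it does not

`generate_ppr_protein` inverts the code table: one scaffold copy per
target symbol with positions 5/35 overwritten by a seeded choice among
pairs mapping to exactly that nucleotide set, motifs tandem at spacing
35.  `generate_ideal_solenoid` builds Cα coordinates from ideal helix
geometry: helix A (12 residues) up, a 4-residue arc loop, helix B (11
residues) antiparallel at 10 Å packing distance, an 8-residue arc
linker to the next motif, motifs stacked at 9 Å — the 35-residue period
matches the protein generator so structure- and sequence-mode
annotation agree on the same residue numbering.  Loop and linker
residues are placed on circular arcs with near-peptide spacing whose
i,i+2 distances (~7 Å) cannot satisfy the helix criteria.  Gaussian
jitter (default σ = 0.1 Å) perturbs all coordinates.
`generate_mito_genome` draws an i.i.d. genome from an AT-rich
human-mito-like composition (A 0.31, C 0.31, G 0.13, T 0.25) at 16 569
bp by default, attaches a 10-gene map, and substitutes planted words
(reverse-complemented on "−").

Passing tests on these inputs show the chain is internally consistent
and statistically calibrated; they do not show that real predicted
structures satisfy the hairpin criteria (real repeats are irregular,
bent, and interrupted by insertions), that the shipped code table
matches any particular protein family's measured specificity, or that
an i.i.d. background captures mitochondrial sequence structure
(codon bias, strand asymmetry, repeats).  Runs on real GenBank genomes
are supported but their biology is not validated here.

Every generator is a pure function of (parameters, seed), using one
named NumPy `SeedSequence` stream per generator; identical calls are
byte-identical.

## Numerical and design choices

- Coordinates are 1-based inclusive throughout (GenBank/FIMO
  convention); U→T at read time so one alphabet serves genome and
  transcript input.
- Circular genomes carry a flag but windows do not wrap, matching the
  scanner the field uses; wrap-around sites at the origin are missed.
- Discretization error: refining granularity 10× changes no p-value by
  more than the coarse bin mass (property-tested).  A zero-range matrix
  (all-N consensus) degenerates to a single bin with p = 1.
- BH q-values are computed directly (step-up with cumulative minimum);
  the test suite cross-checks against statsmodels.
- The chaining DP and the hairpin pairing are both deterministic under
  ties by construction (first-maximum / N-terminal preference).
- Problem sizes in tests and the acceptance script (100 kb calibration
  genome, 16.6 kb end-to-end genomes, 20 seeded runs, 40-repeat
  solenoids) were chosen as the smallest scales at which the measured
  properties are statistically meaningful; all run in seconds on one
  core.

## Known limitations

- Structure mode reads a single chain of CA records; mmCIF, multi-chain
  complexes and altloc-rich crystal structures are out of scope.
- The sequence-mode profile is scaffold-derived, not family-curated; on
  real proteins its motif calls will differ from profile-database tools,
  and no arbitration between structure- and sequence-mode annotations is
  attempted.
- Exact p-values assume the 0-order background; higher-order Markov
  backgrounds and gapped motifs are not supported.
- Per-gene ranking uses the best p-value only; multi-site genes gain no
  rank benefit beyond their count column.
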