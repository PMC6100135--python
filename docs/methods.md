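# Methods

This note documents the models, conventions and numerical choices behind
`mirvicinity`, and what the synthetic-data based tests do and do not show.

## Coordinates and alphabets

All sequence and structure coordinates are 1-based inclusive (miRBase and CT
convention); dot-bracket position *i* is sequence position *i*. Sequences are
normalized at parse time (lowercase → uppercase, T → U); any character outside
{A, C, G, U} is a hard error rather than a silent N — every downstream
statistic assumes a four-letter alphabet. Pseudoknot bracket families
("[]", "{}", "<>", letter pairs) are parsed and retained, but the motif
analysis operates on the nested "()" layer only and treats pseudoknotted
positions as unpaired: the motif vocabulary (bulge, internal loop) is defined
on the nested layer, and the secondary structures this pipeline consumes are
produced by nested-structure predictors anyway.

## Vicinity sequences

A locus qualifies for flank *f* when both its upstream (start − 1) and
downstream (length − end) flanks are ≥ *f*; a record is kept when at least one
locus qualifies, and only qualifying loci contribute vicinity sequences. Both
vicinity sequences are read in **distance order**: position 1 is the
nucleotide adjacent to the miRNA boundary and positions increase moving away
from the miRNA, on both sides. This convention makes "the first position
behind the miRNA" mean the same thing on the 5′ and the 3′ side and matches
the distance semantics of the motif detector; the alternative (reading both
flanks 5′→3′) would silently flip the 5′-side positional statistics.
Evidence classes (experimental / by_similarity / not_experimental) are
carried through but never used as filters.

Frequency tables are raw per-position percentages (probability view), with the
purine/pyrimidine aggregates R = A + G and Y = C + U; no small-sample
correction is applied and no information-content (bit) rescaling is done —
the tables are the numeric equivalent of a probability-mode sequence logo,
and graphical rendering is deliberately out of scope. The pattern census
enumerates all 2^k patterns over {R, Y} including zero counts; the pooled
"total" column uses pooled counts, (c_up + c_down) / (n_up + n_down), not the
mean of the two percentages (distinguishable only when subset sizes differ).
Report output is rounded half-up to 2 decimals (3 for distance tables);
internal values keep full precision.

## Motif detection

From each boundary of a locus the detector walks outward along the structure,
up to `window` nucleotides (default 4, flanks must be ≥ window). It keeps the
last helix pair (a, b) closing toward the miRNA, initialized from the nearest
paired position at or inside the boundary. An unpaired run of length n on the
walked strand, closed by the next pair (q, j₂), faces m unpaired nucleotides
between j₂ and b on the opposing strand: n ≥ 1 and m ≥ 1 is an n–m internal
loop (symmetric iff n = m), exactly one of n, m zero is a bulge. Bulges with
all unpaired nucleotides on the opposing strand (n = 0) are detected when a
walked-strand pair's partner jumps past a gap.

Conventions that the data formats do not fix, chosen here:

* **Distance.** D is the index of the motif's unpaired nucleotide nearest the
  miRNA, counted from the terminus (terminus + 1 ⇒ D = 1). For an
  opposing-strand bulge, D is the distance of the walked-strand pair at which
  the gap is detected. The opposing run's own distance is not measured.
* **Window.** A motif is reported iff its nearest unpaired nucleotide lies at
  D ≤ window; the run may extend past the window and is counted in full.
* **Hairpin exclusion.** A helix continuation must preserve strand
  orientation: sign(j₂ − q) = sign(b − a). A flip with the new pair spanning
  the run means the walk crossed the stem's terminal loop — terminal loops
  are never motifs and the walk stops silently.
* **Junctions.** A flip without spanning the run (a sibling helix), or paired
  positions inside the opposing gap (an inner helix), is a multi-branch
  junction: the walk on that side stops with a logged "junction" sentinel
  rather than a motif call — the bulge/loop vocabulary is two-stranded.
* **Lonely pairs** count as pairs and terminate runs (prediction tools emit
  them; deleting them would move motif boundaries away from the structure as
  given).
* **Deduplication.** With both arms annotated, each physical loop is seen from
  two walks with identical position sets. `find_motifs_all_loci` counts it
  once, keeping the occurrence whose walked strand contains the loop's
  5′-most unpaired nucleotide, so the output is invariant under swapping
  which strand is called miRNA versus miRNA*.

The dataset summary counts, per (motif label, D) cell, the total number of
motifs and the number of distinct structures with at least one; percentages
divide by the number of analyzed **structures** (not loci). "Motif within
distances {1..k}" quotes use the additive convention: the sum of the
per-distance percentages.

## 3D comparison

Fragments overlap the duplex by `in_nt` residues inside and `out_nt` outside
each miRNA boundary (defaults 4 + 4 = 8 residues). Superposition is the
classic Kabsch algorithm (SVD of the cross-covariance of centered coordinate
sets, determinant-corrected to exclude reflections); atom correspondence is
positional, with configurable atom subsets (all common heavy atoms,
backbone, or the C2/C4/C6 base frame). Degenerate inputs (< 3 atoms, or
collinear clouds, rank < 2 at tolerance 1e-8) are rejected.

eRMSD follows the published base-geometry metric: each base gets an
orthonormal frame with origin at the C2/C4/C6 centroid, x toward C2, y the
orthogonalized direction toward C4, z their cross product. The displacement
between base origins, expressed in the first base's frame, is scaled
anisotropically by (5, 5, 3) Å — in-plane, in-plane, normal — giving r̃ with
norm r. For r < r̃_cut = 2.4,

    G(r̃) = ( sin(γr)·x̃/r, sin(γr)·ỹ/r, sin(γr)·z̃/r, 1 + cos(γr) ) / γ,
    γ = π / r̃_cut,

and G = 0 beyond the cutoff; eRMSD(A,B) = sqrt( (1/N) Σ_{j≠k} |G_A(j,k) −
G_B(j,k)|² ) over ordered residue pairs, N the residue count. These constants
are method parameters of the cited metric, restated here because they are
load-bearing. The reference for a set alignment is an explicit index (the
pipeline default is 0); a "random" reference is replaced by a seeded or
user-fixed choice for reproducibility. Note that interactive viewers'
`align` commands typically add sequence alignment and outlier-rejection
cycles; this package's plain all-atom Kabsch will not numerically match them
on real data.

## Synthetic data

`simulate_precursor` builds a single hairpin inside-out: basal stem, upstream
vicinity columns, fully paired duplex, downstream vicinity columns, terminal
loop — planted motifs become unpaired columns at their requested distances
(walked-strand run at D..D+n−1, opposing run placed by the flanking pairs);
overlapping or out-of-window requests are rejected rather than merged.
Defaults (duplex 8 bp, terminal loop 6 nt, basal stem 3 nt, window 4) keep
the worked example small; recovery sweeps and the CLI generator use
duplex lengths of 10–21 bp, matching the 19–24-nt mature miRNA scale. Paired
positions sample Watson–Crick partners with a 10% G-U wobble probability
(configurable) so the alphabet is not unrealistically clean; unpaired
positions sample a global or per-position composition. The duplex itself is
generated fully paired — mismatches inside the duplex are out of scope. The
downstream vicinity gets one guard pair after its outermost motif so a
closing pair always separates it from the terminal loop; upstream, the basal
stem closes the region.

Fragment simulation places a five-atom residue template (P, C1′, C2, C4, C6)
on an A-form-like helix (twist 32.7°, rise 2.81 Å) or on a random coil (6-Å
steps, random residue orientations); the second fragment of a pair is a
uniformly random rotation + translation of the first plus isotropic Gaussian
noise of standard deviation σ per coordinate. All generators run on
`numpy.random.default_rng(seed)`: same seed, same output, on any platform.

What the synthetic data does *not* emulate: thermodynamically realistic
folding (structures are planted, not predicted), prediction noise in
secondary structures, phylum-specific sequence biases, realistic sugar ring
and base atom geometry, and the 2-nt 3′ overhangs of real Dicer products.
Passing recovery tests therefore demonstrates the detector's correctness with
respect to the motif definitions, not robustness to prediction error on real
miRBase data.

## Problem sizes and determinism

The planted-recovery sweep covers motif kinds {1-1, 2-2, bulge-1, bulge-2} ×
both sides × D ∈ 1–4 × 7 seeds = 224 precursors; the oracle comparisons use
20 seeded fragment pairs (a 12-start Nelder–Mead rotation search for RMSD,
a loop-based direct summation for eRMSD); frequency recovery uses 1000
sequences against 3 binomial standard errors. Bundled reference tables (the
5975-structure motif census and the per-phylum 19-fragment distance tables)
make the dataset-level summary statistics reproducible without the external
miRBase snapshot, whose absolute counts are not desk-reproducible and are
covered instead by the property suites (subset monotonicity of the flank
filters, normalization identities, exact planted recovery).

## Known limitations

* Junction handling stops a walk rather than continuing past the junction;
  motifs beyond a junction but inside the window are not reported.
* Opposing-strand gap measurement assumes the locus boundaries pair within
  the hairpin; precursors whose miRNA termini are deep inside large unpaired
  regions anchor the walk at the nearest internal pair.
* CT input carries no bracket families, so pseudoknots encoded in a CT pair
  column are indistinguishable from nested pairs there.
* PDB reading is single-model, single-chain ATOM records with first-altloc
  selection; mmCIF and trajectories are out of scope.
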