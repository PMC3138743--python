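# Methods

## The surface grid

An LRR domain is modelled as a stack of repeats, one grid row per repeat,
one grid column per non-consensus ("x") position of the repeat consensus
motif. Two motifs ship as presets: the generic 24-residue consensus
`xxLxxLxxLxxLxLxxNxLxGxIP` (14 variable positions) and the plant
extracellular consensus `xxLxLxxNxLt/sGxIPxxLxxLxxL` (13 variable
positions, one T/S alternative position). Arbitrary motifs are accepted as
literal text. The five variable positions inside the `LxxLxLxxN` segment —
the β-strand/β-turn region forming the concave face, where most solved
structures bind ligand — are located by matching that pattern against the
motif *cyclically*, because a printed motif may start at any phase of the
repeat; both presets are rotations of the same architecture and yield five
β columns. Cells in the β region are addressable as `N.M` (repeat N, M-th
β position), e.g. `2.3`.

Grid geometry is a plain rectangle: vertical neighbours are the same
position one turn along the solenoid, horizontal neighbours are adjacent
exposed positions within a turn. No wrap-around is applied between the last
column of one repeat and the first of the next; in the folded solenoid
those residues are neighbours along the chain but the published maps treat
rows as independent, and the window already spans both via the row above.

## Repeat detection

Repeats are found by a greedy left-to-right scan. At each candidate offset
the motif is aligned to the sequence by a small dynamic program allowing at
most `indel_budget` (default 2) insertions or deletions; a window is
accepted when at least `min_match_fraction` (default 0.6) of the
fixed/alternative consensus tokens match, with consensus `L` accepting any
of {L, I, V, F, M} (relaxed-leucine matching, standard for LRRs whose "L"
slots tolerate hydrophobics). Insertions are only permitted strictly
between consumed motif tokens, so flanking non-repeat sequence is never
absorbed into a repeat. Accepted repeats are non-overlapping and ordered;
deleted motif positions become HOLE cells, which stay masked throughout.
Residues outside any repeat contribute no grid rows. Detection is
deterministic and reproduces tandem-perfect sequences exactly; irregular
proteins can be corrected with a hand-curation table (TSV of cell
reassignments) that re-validates the monotone N→C ordering.

## Alignment

Homologs are aligned with an internal progressive aligner: pairwise global
Needleman–Wunsch/Gotoh (affine gaps, open 10, extend 0.5, a gap run of
length g costing `open + (g−1)·extend`, terminal gaps penalized), a
neighbor-joining guide tree on pairwise identity distances, and
profile–profile merges in tree order with column scores averaged over all
residue pairs (gap pairs contribute 0). All tie-breaking is lexicographic
by sequence id, so the alignment is independent of input order. The E/F
gap states may follow one another, so the pairwise optimum equals the
exhaustive optimum over all alignments (checked against a brute-force
enumerator in the tests). Pre-aligned input (aligned FASTA or Clustal) is
ingested unchanged, for reproducing externally built alignments.

The grid is defined on one reference protein (the first record unless
`--reference` is given). Homologs with extra repeats contribute those
residues to alignment columns that no reference cell maps to; they are
simply not scored, matching the one-protein-grid semantics of the maps.

## Conservation scores

Raw mode: mean substitution-matrix score over all unordered pairs of the
residues in a cell's alignment column. Weighted mode: mean of

    w(a, b) = clip((S(a,b) − S_min) / (min(S(a,a), S(b,b)) − S_min), 0, 1)

with `S_min` the matrix minimum over the 20 standard residues. This
normalization maps identity to exactly 1 and the most dissimilar
substitution to 0, giving the heat-map scale fixed endpoints; it also makes
a cell score 1.0 if and only if all members are identical there (for
diagonal-dominant matrices, which is checked with a warning). A pair
involving a gap scores 0 (weighted) or `S_min` (raw) under the default
`score` gap policy — an indel at an exposed position is treated as
evidence of non-conservation; `--gap-policy exclude` drops gap pairs
instead and masks cells with no surviving pair. Ambiguity codes use their
matrix entries where present and fall back to `X`.

Default matrix BLOSUM62; BLOSUM65 and the rest of the BLOSUM family are
selectable by name (biopython's matrix set, supplemented by biotite's
database), and the matrix id is recorded in every output. Pair averages
are summed over sorted values, so grids are bit-identical under any
permutation of family members.

## Regional smoothing

The regional score of a cell is the weighted mean of the cell scores in
the window centered on it. The default kernel is 5 × 5 (25 cells spanning
five repeats) with integer weights decreasing by Chebyshev ring distance
from the center: 4 (center), 2 (first ring), 1 (second ring). The center
thus contributes 4/36 ≈ 11% — between the 4% of a uniform window (which
over-smooths and loses resolution) and the 100% of a center-only window
(which degenerates to the unsmoothed cell scores). Uniform, center-only
and Gaussian kernels and other odd window sizes are available; the kernel
is written into the run manifest.

Edge policy: windows are truncated at grid borders and at masked cells and
the surviving weights renormalized, so border repeats receive scores
without inventing padded data. Every regional score is therefore a convex
combination of real cell scores and lies within their range; with the
center-only kernel the regional map equals the cell grid exactly, and with
the uniform kernel it equals a brute-force window mean (both are test
invariants, the latter to 1e-12 on random grids).

## Evaluation

All unmasked scores of a map are ranked descending (ascending in
divergence mode) with positional (row, column) tie-breaks; the cell at
rank r of n gets decile `ceil(10·r/n)`, so decile sizes differ by at most
one. Annotated contact cells are tallied per decile for each score stage
(raw, weighted, regional) and the top-decile and top-two-decile fractions
reported. Contact cells are additionally compared against all other
unmasked cells with a pooled-variance Student's t-test; the claim is
directional (contacts score higher), so the one-sided p-value is the
headline number and the two-sided value is reported alongside.

## Synthetic families

The generator emits a star-topology family: member 1 is a perfect repeat
realization of the motif (fixed tokens emit their residue, alternative
tokens draw uniformly among their alternatives, wildcards draw uniformly
from the 20 standard residues minus the motif's consensus residues, so
wildcard draws cannot mimic consensus positions); every other member
copies it and independently resamples each variable cell with the
background mutation probability — except a designated patch of cells
resampled at its own rate (default 0, i.e. perfectly conserved).
Consensus positions are never touched. A frequency-weighted draw
(Robinson–Robinson amino-acid frequencies) is available; the uniform
default maximizes contrast and keeps the null simple. All randomness flows
from one integer seed through a counter-based generator (numpy Philox),
so families are bit-reproducible.

What the generator emulates: conserved functional patches on an otherwise
drifting exposed surface, irregularities (via curation or planted indels),
and families of 2–10 members. What it does not emulate: phylogenetic
structure (no tree — the pairwise scoring implicitly assumes a star),
natural residue covariation, indel-rich loop regions, or the biased
composition of real LRR surfaces. Passing the synthetic recovery tests
therefore shows the machinery extracts a planted conservation signal at
realistic noise levels; it does not by itself certify performance on real
receptor families, where input choice (orthologs vs diversified paralogs)
dominates.

The default study conditions — 20 repeats, 4 members, background rate 0.5,
one 3 × 3 patch of variable cells placed mid-grid (repeats 10–12, variable
columns 6–8 of 14) — are the package's standard benchmark, run over 20
seeds by the acceptance script and test suite. Patch-vs-background
significance uses the one-sided t-test at p < 0.005; the null check uses a
matched permutation test over random 3 × 3 blocks, which respects the
spatial autocorrelation the smoothing introduces. These sizes keep a full
20-seed study under ten seconds while giving each map 280 cells (28 per
decile).

## Numerical choices and degenerate inputs

* Scores are float64 throughout; TSVs print `%.10g` and round-trip to
  identical files.
* Rank and decile ties break by (repeat, column) position — deterministic,
  and conservative for the patch statistics since planted patches sit
  mid-grid behind any earlier tied cells.
* A motif without wildcards parses (with a warning) but refuses grid
  construction; a sequence shorter than the motif is an error, a sequence
  with no acceptable repeat window yields an empty annotation with a
  warning.
* A flat map renders as a single-colour panel (the relative colour scale
  widens a degenerate range); `--absolute-scale` fixes the scale to [0, 1]
  for cross-map comparison.
* Renders are byte-deterministic (fixed Agg backend, no volatile
  metadata), and every run writes a manifest (input digests + all
  parameters) from which `rerun_from_manifest` reproduces all outputs
  bit-identically.

## Known limitations

* Repeat detection is heuristic; heavily irregular domains (long
  intervening loops, capping domains) need hand-curation, as the original
  workflow also anticipated.
* The progressive aligner is exact only pairwise; profile merges are
  greedy in guide-tree order, which can differ from external aligners on
  gappy families — pre-aligned input is the escape hatch.
* The weighted-score normalization is one reasonable mapping of
  substitution scores onto [0, 1]; alternatives (entropy, phylogeny-aware
  weighting) are deliberately out of scope because the method's validation
  statistics are defined on unweighted pairwise scores.
* Divergence-mode reading is supported by ranking direction only; no
  separate statistic distinguishes "diversified" from "unconserved".
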