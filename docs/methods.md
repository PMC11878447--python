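# Methods

## Problem and data model

A Ringer profile is a vector of electron-density values, in map σ units,
sampled at uniform angular steps over one full rotation of a side-chain χ
dihedral. One structure contributes one profile per (residue, χ); glycine
and alanine contribute none. Chains of multi-copy structures are treated
as separate models throughout, so crystal-lattice microenvironments remain
separate lines of evidence. The angle grid is inferred from the CSV (step
= 360/number of σ fields) and stored as an exact rational, so grids whose
step is not a whole degree remain exact; all profiles being compared must
share one grid, and the package refuses to mix grids rather than
resample.

## Sequence extraction and alignment

Sequences are read off the profile sets in author-residue-number order.
Because Ringer output omits Gly/Ala and unbuilt stretches, the extracted
sequences have holes; by default the extraction mirrors that faithfully,
since those holes are part of what the alignment must absorb. An optional
fill mode replaces every missing integer residue number with 'X'
(provenance `UNK`), which can help the aligner bridge Gly/Ala-rich
stretches; filler cells never match a profile and therefore stay inert in
all downstream statistics.

Alignment engines:

* **external** (recommended for real comparisons): any MUSCLE-compatible
  executable via `<aligner> -align in.fasta -output out.fasta`, with a
  `v3` dialect hook (`-in`/`-out`). The subprocess's stderr is carried
  into the error on failure.
* **builtin**: progressive alignment over pairwise global
  Needleman–Wunsch with the Gotoh affine-gap recurrence. Scoring is
  BLOSUM62 with gap open −10 and extend −1, where a gap of length k costs
  open + (k−1)·extend; 'X' scores 0 against everything. The guide order
  is by descending pairwise identity; each further sequence is aligned
  against the growing profile, a letter scoring the mean BLOSUM62 score
  over a column's non-gap letters. Traceback ties are broken
  deterministically: diagonal, then gap-in-second, then gap-in-first.

Whichever engine runs, the output is validated: ungapping every row must
reproduce the input sequence exactly (hard error naming the first
mismatch). Alignment columns are 1-based everywhere. The column ↔
(chain, residue number, insertion code) look-up is saved as CSV, and the
alignment FASTA can be hand-edited and reloaded; edits may move gaps but
any deletion or mutation of a letter is rejected. Engine equivalence is
deliberately not asserted — alignment heuristics differ — only residue
conservation, lookup bijectivity and column monotonicity.

## Peak detection on the circle

A peak is a sample strictly greater than both circular neighbours;
plateaus count once at their leftmost sample (leftmost meaning the first
sample of the run when entering it clockwise from a lower value, which is
well defined as long as the profile is not constant; a constant profile
has no peaks). Candidates below `threshold_sigma` are discarded. The
default threshold is **0.3σ**, the accepted evidence level for alternate
conformers in 2mFo−DFc maps; 1σ is the conventional single-conformer
modeling threshold and is drawn on every plot for reference. Remaining
peaks closer than `min_separation_deg` (default **30°**, about one rotamer
well) are merged keeping the higher peak, ties keeping the smaller angle;
all distances wrap at 0°/360°. An optional circular moving average
(`smooth_window`, odd, default off) runs before detection. A separation of
≥180° is rejected because it would merge opposite rotamer wells.

The signed per-residue statistic is simply the difference of peak counts
between two models at one aligned residue and χ; it is antisymmetric and
requires both peak sets to have been produced at the same threshold.

## Correlations and medians

Pearson CCs are computed on the raw, unclipped σ vectors (no smoothing, no
floor) as sign(c)·sqrt(c²/(SaSb)) on centred vectors — algebraically the
product-moment formula, but exact at ±1 for perfectly (anti)correlated
inputs. A CC is undefined for constant profiles or fewer than 3 samples
and is excluded from medians rather than imputed, since imputation would
fabricate similarity. Per column, the reported `median_cc` is the median
over all defined pairwise CCs across the requested χ angles (numpy
median: even counts average the central pair); per-χ medians are also
kept because χ1 and χ2 maps are often inspected separately.

## Surface output

Per-residue values (median CC, or a signed peak-count difference for a
chosen model pair and χ) are written into the temperature-factor field
(columns 61–66, `%6.2f`) of every ATOM/HETATM record of a template PDB,
matched on (chain, author residue number, insertion code); all altlocs of
a residue receive the same value. Every other byte of the template is
preserved. Unscored residues get the sentinel −1.00 so they are visually
distinct from a genuine CC of 0; values outside the field range are
clamped with a warning. Plots default to SVG with a fixed hash salt and no
date metadata, so identical inputs give byte-identical files.

## Synthetic fixtures

The generator emulates the level of structure this pipeline actually
consumes — not electron density itself. Each (residue, χ) profile is a sum
of wrapped Gaussians (wrapped by summation over ±1 turn; width is the
Gaussian σ in degrees) centred on rotamer angles 60°/180°/300°, plus
i.i.d. Gaussian noise per sample, with an optional truncation floor
mimicking map noise near zero (off by default). A homolog pair shares one
base construction and differs by a renumbering offset, substitutions,
deletions and planted extra (or removed) rotamer peaks, all recorded in a
ground-truth table of per-(residue, χ) peak counts and signed differences.

Default conditions: 100 residues on a 5° grid (72 samples), offset +11,
10 residues with a planted extra χ1 peak, per-sample noise σ = 0.05,
planted peak heights 0.5–0.9σ. Primary rotamer peaks are drawn at
3.5–4.5σ with width 10°, representative of well-ordered side chains in
high-resolution 2mFo−DFc maps. The shape parameters were fixed by design
calculation before freezing: with width 10°, the above-0.3σ flank of even
a 4.5σ peak ends ~23° from the centre, inside the 30° merge radius, so
noise on a peak's flank cannot spawn a second countable peak (wider or
shorter peaks violate this and make planted counts ambiguous); and the
resulting profile variance keeps the sample CC of unchanged residues
above 0.99 at noise 0.05 with comfortable margin. Under these conditions
peak-count recovery through the entire pipeline is exact and is exercised
as such in the test suite and the acceptance script.

What the generator does **not** emulate: resolution-dependent peak
broadening, correlated noise along the rotation path, backbone-dependent
rotamer preferences, occupancy-weighted peak heights, or cross-structure
σ-scale differences. Passing tests therefore demonstrate the correctness
of the bookkeeping and statistics, not detection power on real maps; on
real data, σ comparability across structures remains the user's
responsibility and thresholds may need adjustment with resolution.

## Numerical and design choices

* Duplicate (residue, χ, map-type) rows in one CSV are a hard error — the
  format gives no way to choose between them.
* Residues are ordered by author numbering; file order is not trusted.
* Non-standard residue names map to 'X' via a documented 3→1 table
  (MSE→M and the selenium/pyrrolysine codes are honoured).
* CC on raw values and unclipped negatives: clipping would inflate
  correlations between weak profiles.
* Problem sizes in the test suite and acceptance script (1000 oracle
  profiles, a 100-residue pair, 15 exhaustively enumerated alignment
  pairs of length ≤ 8) are chosen so the full suite completes in seconds
  while still covering every code path end to end.

## Known limitations

* The builtin aligner is a plain progressive scheme with no iterative
  refinement; for distant homologs use the external engine or hand-edit
  the alignment (the reload path validates edits).
* Multi-model B-factor output targets one template at a time; mapping a
  three-way comparison onto one structure collapses it to that model's
  residues.
* Insertion codes are carried through the lookup but the synthetic
  generator never emits them; they are covered by parser tests only.
* mmCIF templates and map-file input are out of scope (the package
  consumes Ringer CSV output, it does not sample maps).
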