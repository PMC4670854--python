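# Methods

## Hairpin model and arm alignment

A precursor is accepted only if its dot-bracket structure is a
single-stem hairpin: exactly one innermost loop (one `(` followed, across
unpaired positions only, by `)`). Multi-branched structures are rejected
outright rather than approximated, because every downstream definition
(arms, duplex window, loop distance) presumes two arms around one
terminal loop.

The two arms are laid out as a gapped two-row alignment by a two-pointer
walk from the sequence ends toward the loop: mutually paired positions
form a paired column; an unpaired position forms a one-sided column with
an explicit gap opposite. Two conventions are fixed here and matter for
feature determinism:

- **Internal-loop tie-break.** When both pointers sit on unpaired bases,
  all 5′-side columns are emitted before the 3′-side ones. Any fixed
  order would do; this one is frozen so that feature vectors are
  reproducible across runs and versions.
- **No double-sided unpaired columns.** A mismatch therefore renders as
  a 1×1 internal loop — one `(base, gap)` column plus one `(gap, base)`
  column. The double-gap state in the feature alphabet never arises from
  the alignment itself; it encodes alignment gaps within feature slots,
  while code 0 marks slots beyond the available data (padding, virtual
  upstream slots, flanks falling off the precursor).

Sequences are uppercased and T→U mapped on ingest; IUPAC ambiguity codes
are rejected with an explicit error. Coordinates are 0-based half-open
internally and 1-based inclusive in every file format (miRBase
convention); `maturescan.io` is the only crossing point.

## Duplex-window geometry

For a putative mature start on the 5′ arm, the window is defined in
*alignment-column* space: it begins 2 columns basal of the mature-start
column and spans the mature length (default 22) in columns. Column
arithmetic — rather than nucleotide arithmetic — is what makes the
boundary scenarios well-defined: a window boundary can land on a column
whose 5′ side is a gap, and the rules then adjust it so that both
boundaries always carry 5′-arm nucleotides:

- **S1** — the window would begin before the precursor: the absent
  upstream positions become virtual slots encoded 0.
- **S2** — the end column is a 5′-side gap: the end slides loop-ward to
  the next 5′-arm nucleotide.
- **S3** — the start column is a 5′-side gap: the start slides loop-ward
  to the next 5′-arm nucleotide and the end re-anchors so the window
  holds `mature_len` 5′-arm nucleotides counted from the pre-shift
  column.
- **S4** — the unadjusted standard case.

Precedence when conditions co-occur: S3 before S2; S1 padding is applied
last (a window may carry virtual slots while tagged S2). On a perfectly
matched stem the standard window spans 24 columns and therefore contains
48 nucleotides.

A 3′-arm mature, written 5′→3′, runs loop→basal; its basal-most
nucleotide sits opposite the position that plays the role of the mature
start in 5′-arm geometry. The same column rules are applied at that
anchor, so a 3′-arm candidate and the 5′-arm candidate at the same
column span describe the *same duplex* and receive identical features.
Consequences drawn from this symmetry:

- **Training** deduplicates rows by duplex (column span + padding); a
  duplex matching an annotated mature on either arm is the positive.
  Without deduplication every positive would have an identical-feature
  negative twin, which provably corrupts the margin. Deduplication also
  yields ~(arm length − mature length) negatives per precursor, the
  regime the method was designed for.
- **Prediction** ranks candidates per arm; the model cannot, by
  construction, distinguish which strand of a duplex is loaded, so
  evaluation scores each annotated mature against the best candidate on
  the *annotated* arm and reports a separate wrong-arm flag when the
  overall best sits on the other arm (on arm-symmetric synthetic data
  that flag fires ~50% of the time, as expected).

## Features

Layout (94 = 60 + 18 + 6 + 9 + 1), frozen as
`maturescan-94-v1` and checked on model load:

| slots | content |
|---|---|
| 1–60 | window states, interleaved (5′, 3′) per column, basal→loop |
| 61–78 | 9 lower-stem columns basal of the window, nearest-first |
| 79–84 | 3 columns loop-ward of the window end |
| 85–93 | MFE1…MFE9 (kcal/mol) |
| 94 | nt from window start to the terminal loop |

State codes: 1–4 = A/C/G/U paired, 5–8 = unpaired, 9 = gap, 0 =
missing/padding. Integer codes (not one-hot) feed the kernel; windows
longer than 30 columns (possible with many bulges) are truncated
loop-ward so the Drosha-side geometry is preserved.

MFE regions are the window plus 0/3/5/9 columns basal ("upstream of the
Drosha site", taken as the window's basal boundary) and plus 3 columns
loop-ward, clipped at the precursor and the loop. Each region's energy is
the two-strand cofolding MFE of the region's 5′- and 3′-arm segments
(gaps removed, 3′ strand read 5′→3′), computed with ViennaRNA 2.7.2;
cofolding is used because the regions are two disjoint strands by
definition — refolding through the loop would contradict the basal
extensions, which exclude the loop. An empty or one-sided region after
clipping scores 0 with a logged warning. The engine version is recorded
in model metadata because MFE values and dot-brackets can change across
engine versions.

The loop distance (slot 94) is the half-open nucleotide count from the
window's first 5′-arm nucleotide to the loop start; it is invariant to
basal-segment length.

## Classifier

`SVC` (libSVM via scikit-learn) with the RBF kernel. Choices where the
method description is silent, made once and recorded:

- **Scaling:** per-feature min–max to [0, 1], computed on training data
  only and stored in the model (standard libSVM practice).
- **Class imbalance:** with one positive against ~15–25 negatives per
  precursor, `class_weight="balanced"` keeps the hinge loss from
  collapsing onto the majority class.
- **Model selection metric:** mean per-precursor *exact-hit rate* (the
  top-ranked duplex of a held-out precursor is the true one) under
  grouped cross-validation — row-wise accuracy is degenerate at this
  imbalance, and whole precursors are held out so a precursor's positive
  never informs the scoring of its own negatives. Folds are formed by
  seed-shuffled round-robin assignment of precursors; ties in the grid
  prefer the first combination in (c, γ) iteration order.
- **Grids:** c ∈ 2⁻⁵…2¹⁵ and γ ∈ 2⁻¹⁵…2³ on a ×2⁴ ladder (6 × 5
  combinations). A coarse ladder suffices here because selection is by a
  per-precursor ranking metric that is flat over wide (c, γ) plateaus;
  both grids are user-settable.
- **Probabilities:** a Platt sigmoid p(+|f) = σ(a·f + b) fitted on
  out-of-fold decision values with Platt's target smoothing (the usual
  libSVM `-b 1` convention). Probabilities are therefore monotone in the
  decision value and the pair sums to 1 exactly.

The serialized model is a single JSON file holding the support vectors,
dual coefficients, intercept, (c, γ), scaling bounds, calibration
parameters, feature-layout version and folding-engine version. JSON
round-trips IEEE doubles exactly (shortest-repr), so reloaded models
reproduce decision values bit-for-bit, and re-training with the same seed
produces a byte-identical file.

## Synthetic benchmark

The generator emulates miRBase-style precursors: a stem of 30–50 5′-arm
nucleotides with per-column background corruption (bulge 0.05, mismatch
0.08), a 4–12-nt terminal loop, a 0–8-nt basal segment and a 2-nt 3′
overhang. Structures are emitted as-built (ground-truth pairing), so
structural features are fully controlled; `refold=True` exercises the
folding path instead.

Each precursor carries one planted mature (either arm, equal odds). Its
start sits `loop_distance_target` nt upstream of the loop — default 24,
placing the mature 3′ end 2 nt short of the loop, the canonical Dicer
geometry; note the start-to-loop distance of a 22-nt mature can never be
below 22 — plus positional noise drawn from {−1: 0.15, 0: 0.70,
+1: 0.15} (mostly-exact cleavage with occasional 1-nt slippage, matching
the end-heterogeneity seen in real data).

Position alone is deliberately not enough to recover the site at 1-nt
resolution: position enters the feature vector through a single
dimension, and after min–max scaling no isotropic kernel can resolve a
±1-nt bump along one axis out of 94 without memorizing. Real processing
sites are instead marked by local sequence/structure determinants, which
is precisely what the position-specific state features exist to capture.
The generator therefore plants such determinants at the site: a 5′-U at
the mature start (the base AGO loading favours), a well-paired duplex
with a single mismatch at duplex offset +10 (a central internal loop),
and an enforced-paired 2-nt shift region basal of the start. The planted
region is corruption-free by design, so the background-rate convergence
check counts columns outside it. A `plant_site_determinants=False` switch
yields geometry-only hairpins for structural tests.

What passing the recovery benchmark shows: the pipeline can learn a
localized sequence/structure signature and rank the true duplex first on
unseen precursors (exact-hit 0.98, AD 0.02 nt at train 150 / test 50
under default conditions). What it does not show: performance on real
precursors, whose determinants are weaker, partially redundant and
entangled with composition biases the generator does not model
(no dinucleotide realism, no G·U wobble pairs in constructed stems, no
miRtron geometries, no multi-mature precursors).

## Numerical and degenerate-input conventions

- Ranking ties in probability break toward the basal-most start, so
  outputs are stable.
- A precursor whose arms cannot host any window yields an empty result,
  not an error; multi-stem inputs raise.
- Empty MFE regions score 0 (logged); constant features get unit range
  during scaling to avoid division by zero.
- Fold/cofold, grouped folds, SVC fitting and the Platt fit are
  deterministic given the seed; the SMO optimizer's convergence
  tolerance (~1e-3) is the only source of run-order sensitivity, and the
  row order is itself deterministic.
- Problem sizes in the shipped tests (200-precursor benchmark, 150/50
  split; 500-hairpin robustness sweep; 900-precursor rate check) were
  chosen to give stable statistics at interactive runtimes.

## Known limitations

- The 3′-arm window convention (anchor at the partner of the mature's
  basal-most nucleotide) is one of several defensible mappings; it is
  isolated behind `build_window` so it can be swapped.
- Which strand of a predicted duplex is the loaded mature is not
  modelled; both arms are reported with the wrong-arm flag left to the
  caller.
- Negative enumeration uses every valid arm position; no subsampling is
  performed at training time.
- Wobble (G·U) pairs occur in refolded structures but are never planted
  by the generator's constructed stems.
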