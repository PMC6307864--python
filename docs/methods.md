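# Methods

This note records the models, parameter choices and known limitations behind
each stage of the pipeline, and what the synthetic benchmarks do and do not
establish about behaviour on real data.

## Reference schemes and site mapping

All residue rules are written against fixed positions on two reference
proteins: the mature rat GluA2 subunit (iGluR scheme; "mature" means the
signal peptide is removed, so the Q/R site is position 586) and human mGluR1
(positions 78 and 409). The packaged scheme sequences are **synthetic
stand-ins**: 862- and 900-residue deterministic backgrounds with the
canonical residues planted at the canonical positions (iGluR: Glu423,
Arg485, Gln586, Asp590, SYTANLAAF at 600–608, Gly653, Thr655, Glu705;
mGluR: Arg78, Lys409 and seven 21-residue hydrophobic helices starting at
580, separated by 15-residue polar loops). Only the positions and the
planted identities carry meaning; the background is random and is labelled
as such in the data files. Users with access to the real sequences can
supply them via `load_scheme(scheme_yaml=...)` — every downstream rule reads
positions, not background.

Mapping is a global Needleman–Wunsch alignment with affine gaps (BLOSUM62,
gap open 11, extend 1 — the familiar protein-search defaults; a gap of
length L costs 11 + L). The aligner is implemented in-house (row-vectorised
Gotoh with three state matrices; the horizontal-gap state is computed with a
running-maximum scan so each row is a handful of numpy operations) because
the screen and the mapper both need raw scores under a controlled
convention; tests cross-check it against exhaustive alignment-space
enumeration and against Biopython's `PairwiseAligner`. Coverage (fraction of
reference positions aligned to query residues) below 0.30 flags the
assignment `low_homology` — a warning, never an exception, because
fragmented gene models are common and their site readings may still be
informative. Residues aligned to a gap are reported as `-` and fail every
downstream residue test.

The dominant failure mode of site mapping is an indel immediately adjacent
to a diagnostic site: the optimal alignment may then place the gap on the
reference's site column rather than its neighbour (the two placements can
be score-equivalent), and the site reads as a gap. Under point substitution
alone recovery is complete at low divergence; with single-residue indels at
a quarter of the mutation rate, a site is occasionally lost this way (for
example 29/30 planted sites recovered in one seeded acceptance sweep at
mutation rate 0.02). This mirrors real practice, where site readings next to
alignment gaps deserve manual inspection.

## Quality filters

* **Gating motif.** Conservation of SYTANLAAF is counted positionally at
  the mapped motif columns (identity; a similarity-group mode is available
  behind a flag, since how "conserved" was originally counted is not
  recorded). Queries whose mapped motif region is entirely gapped fall back
  to a best sliding-window scan, flagged `location_method="scan"`. Fewer
  than 4 conserved residues discards the sequence; 4 keeps it.
* **Transmembrane counting.** Kyte–Doolittle hydropathy averaged over a
  19-residue window, threshold 1.6 — the classical single-sequence heuristic
  (window and threshold are config keys; no method was named for the
  original analysis, and no HMM topology predictor is used). Runs of
  above-threshold windows merge when separated by fewer than 5 window
  positions. An mGluR keeps its place with ≥ 6 detected helices ("lacking
  two or more of the seven" discards). `X` scores 0.0 in profiles and
  counts as a mismatch in motif columns.

## Residue-rule engine

The cascade (first match wins, trace recorded):

| rule | condition | call |
|------|-----------|------|
| R1 | not (Arg485 and acidic 705) | no_amino_acid |
| R2 | Arg653 | glycine (confident; Glu423 salt bridge annotated) |
| R3 | Tyr653 | blocked_tyr653 |
| R4 | Ser653 + non-polar partner | glycine (confident) |
| R5 | G/S/T 653 + Thr655 | glutamate (confident) |
| R6 | D/E at both 653 and 655 | candidate_glutamate |
| R7 | Gly653 + non-polar partner | candidate_glycine |
| R8 | Phe at 653 or 655 | unclassified_phe |
| R9 | otherwise | unknown |

Design choices that were genuinely open:

* **Precedence.** R2 and R3 precede R4/R5 so the two structurally decisive
  signatures (the ctenophore-style arginine and the pocket-occluding
  tyrosine) dominate; the order is a visible constant and appears in every
  `rule_trace`.
* **"Negative polarity"** at 653/655 is read as D/E; N/Q can be added via
  the `negative_polarity` set.
* **Position 704.** Epsilon receptors appear to present the glycine rule's
  non-polar partner at 704 (e.g. a tryptophan) while the general rule reads
  655. The non-polar test site is a flag (`655` default, `704`, `either`);
  704 is always mapped and recorded regardless.
* **Non-polar set** {A, V, L, I, M, F, W, P, G}, configurable.

Channel character: `rectification_flag = (Gln586 and acidic 590)` — the
unedited-AMPA/Kainate signature for calcium permeability and polyamine
block. mGluRs: Arg78 + Lys409 → glutamate-competent; a non-polar or acidic
replacement at either → incompetent; anything else → unknown.

## Homology screen

Forward search of each candidate against the GluR query set; best E-value
below 0.05 admits the candidate to a reciprocal search against a labelled
database; acceptance requires the reciprocal top hit (self-hits excluded,
ties broken by E-value, then bit score, then subject id — tie handling was
unspecified, so it is deterministic and logged) to carry the `GluR` label.
E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041. Searches of
genome/transcriptome assemblies by an external engine enter through
`TabularBackend` (12-column tabular reports); the decision logic is
identical by construction and by test.

**Decoy-benchmark caveat.** Because the E-statistics are calibrated, a
composition-shuffled decoy clears the forward gate with probability ≈ the
threshold (~5%), and *conditional on clearing it*, the reciprocal top hit is
often the very GluR that produced the low E-value — the two events are
strongly correlated. In the real procedure the reciprocal database is the
non-redundant protein database, whose overwhelming non-GluR majority breaks
that correlation; a desk-scale database (3 GluRs + 40 unrelated proteins,
~25k residues) cannot. At the benchmark's fixed seed the decoy acceptance is
0/20 with 20/20 planted homologs accepted; across other seeds 0–2 of 20
decoys slip through, and `scripts/acceptance.py` reports whatever the run
produced. Scaling the unrelated fraction up narrows this further at linear
compute cost; the benchmark sizes here keep the full screen under half a
minute on one CPU.

## Tree surrogate

p-distance with pairwise deletion (a pair sharing no ungapped column is an
error), Kimura's protein correction `d = −ln(1 − p − 0.2p²)` (saturated
pairs, p ≥ 0.85, are capped at a configurable 5.0 with a warning rather than
aborting), Saitou–Nei neighbor joining (Q-criterion; ties broken by lowest
index pair; negative branch lengths clamped to zero with a warning),
outgroup rooting on the branch above the outgroup's common ancestor, and
label propagation: each query takes the class of the smallest rooted clade
containing it and at least one reference leaf, provided all reference leaves
in that clade agree; mixed clades yield `unassigned`; outgroup leaves confer
no class. Per-class reference monophyly is flagged.

The surrogate deliberately replaces Bayesian/ML inference for *count-level*
claims on deep, well-separated splits (AMPA vs Kainate). It does not produce
support values, does not use the original substitution models, and is not
expected to resolve shallow or conflicted splits — those remain the province
of the exported alignments (PHYLIP/FASTA) and external tools. NJ is exact on
additive matrices, which is what the topology-recovery tests exploit.

## Synthetic data

`generate_family` plants sites, an exact motif-conservation count and a TM
layout on the template, then applies seeded point mutations and
single-residue indels outside the protected positions (all scheme sites, the
motif window, the TM helices). Replacement residues follow
BLOSUM62-conditional weights `P(b|a) ∝ exp(0.267·S(a,b))` so distances
behave like protein evolution; uniform replacement is a flag. One
`numpy.random.default_rng(seed)` per call; no global state; output is
bit-identical per (spec, seed).

Default study conditions: mutation rate 0.02 ("low noise", within-family
divergence), with 0.05 and 0.10 used as stress levels in the recovery
benchmarks; families of 5–20 sequences; decoys 150–400 residues drawn iid
from the reference composition. The two-lineage protostome-style benchmark
generates class templates 12% diverged from the base, members 3% diverged
from their template and a 25%-diverged two-leaf outgroup, at the published
composition of 40 + 15 lophotrochozoan and 10 + 40 ecdysozoan AMPA/Kainate
queries.

What passing these benchmarks shows: the mapping, rules, filters, screen
logic and tree machinery are internally correct and recover planted truth
under realistic point-substitution noise. What they do not show: robustness
to the full messiness of real gene models — long lineage-specific
insertions, fragmented assemblies, compositional bias, rate heterogeneity
across sites, or classes whose true history is not tree-like at the
surrogate's resolution. The published-count reproduction test exists for
exactly that reason and runs whenever the deposited alignments are placed
under `data/source_data/`.

## Numerical notes

* All alignment scores are sums of integer matrix entries and integer gap
  costs held in float64, so score comparisons in tracebacks use an absolute
  tolerance of 1e-6 safely.
* `neighbor_joining` requires ≥ 3 taxa; the final three-way join solves the
  three-point equations exactly.
* Newick output always carries branch lengths and prints integral lengths
  with a decimal point (`1.0`), so round-trips through standard parsers
  preserve lengths to 1e-9.
* Problem sizes in the test-suite benchmarks (families of 5–50, 200
  sequences for TM-count accuracy, 8-taxon topology sweeps, a 113-leaf NJ
  run) were chosen to exercise each property at the smallest scale where
  the statistics are meaningful; the full acceptance sweep runs in about
  half a minute.
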