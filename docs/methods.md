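# Methods

This note records the model implemented by `softdis`, the parameter
choices with their rationale, the numerical decisions, and the known
limitations.  No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` actually compute.

## 1. Soft-disorder model

A residue in one crystal chain is **soft** if it is *missing* or
*flexible*:

- **Missing**: listed in the construct sequence (SEQRES) but absent from
  the ATOM records.  Missing residues are recovered from REMARK 465 in
  PDB files, or inferred from gaps in the label-sequence mapping in
  mmCIF.  For coordinate files without SEQRES, gaps in author numbering
  are treated as missing.
- **Flexible**: normalized Cα B-factor strictly above 3,
  `b_i = (B_i − mean(B)) / σ(B) > 3`, with mean and *population*
  standard deviation over the chain's Cα atoms.  Population σ (divisor
  `n`) is chosen because the chain is the entire population of interest,
  not a sample; for a constant-B chain (σ = 0) all `b_i` are defined as
  0 and nothing is flagged.  A residue cannot be both missing and
  flexible; the annotation object enforces this invariant.

Chains of the same sequence family are aligned to a representative and
counted per aligned position:

- `freq_soft(i) = n_soft(i) / n_aligned(i)`,
- positions with `n_missing == n_aligned > 0` are **ID** (intrinsically
  disordered): always unresolved, hence uninformative about conditional
  flexibility.  Their frequency is NaN and they are masked downstream.
- category labels: `ID`; `SD,DtO` when at least one chain has the
  position missing and at least one resolved; `SD` when only high-B
  events occur; `none`; `unaligned`.

The **representative** of a family is the chain of the entry with the
best (smallest) resolution, ties broken by reported R-value, then by
identifier for determinism.  Greedy clustering anchors on the longest
sequence, so after clustering the profile is re-anchored on the
best-resolution member by re-aligning all members to it.

A downstream binary label per position is `1` if the position was soft
in at least one chain (`freq_soft > 0`), `0` otherwise, with ID and
unaligned positions masked.

## 2. Sequence clustering

- Pairwise alignment: `Bio.Align.PairwiseAligner`, BLOSUM62, gap open
  −11 / extend −1, global mode with free end gaps (end-gap scores 0) so
  that fragments align to full-length chains without terminal penalties.
- Identity = identical aligned pairs / length of the shorter sequence
  (the CD-HIT convention); coverage of each sequence = aligned (matched)
  positions / its length.
- Greedy incremental clustering, sequences sorted longest-first (ties by
  key for determinism): a sequence joins the first existing cluster
  whose anchor it matches at ≥ the identity threshold with ≥ the
  coverage threshold on both sequences, else founds a new cluster.
  Family building uses 90 % / 90 %; dataset redundancy reduction uses
  50 % identity / 80 % coverage; leakage pruning removes val/test
  records whose best identity to any training sequence is ≥ 30 %.

## 3. Interfaces and accessibility

- **Protein contacts**: two residues in different chains are in contact
  if their Cα atoms are within 5.0 Å *inclusive*.  Implemented with a
  `scipy.spatial.cKDTree` over all Cα atoms; verified against an O(n²)
  brute force in the tests.
- **Solvent-accessible surface area**: Shrake–Rupley with a
  deterministic Fibonacci-sphere lattice (default 1024 points per atom),
  probe radius 1.4 Å, and NACCESS van der Waals radii (C 1.87, N 1.65,
  O 1.40, S 1.85, P 1.90 Å).  1024 points give a mean relative change
  below 0.5 % (max < 2 %) versus a 2048-point lattice on random chains,
  and machine-precision agreement with the analytic area of an isolated
  sphere.  The lattice is deterministic so results are bit-reproducible.
- **Nucleic interfaces**: a protein residue is interfacial to a nucleic
  chain if its ASA drops by more than ε = 0.01 Å² when the nucleic
  chains are added to the protein.  The epsilon absorbs lattice noise;
  areas below it are not meaningful at 1024 points.

## 4. Dataset construction

Profiles become per-residue records (sequence, binary labels, frequency
labels, ID/unaligned mask).  Pipeline defaults:

- length filter 20–2048 inclusive (shorter chains are mostly peptides,
  longer ones exceed common predictor input limits);
- redundancy reduction at 50 % identity / 80 % coverage, keeping each
  cluster's representative;
- random 70/10/20 train/val/test splits using
  `numpy.random.default_rng(seed).permutation`, with exact subset sizes
  by largest-remainder rounding, so 1000 records always split
  700/100/200 and the assignment is reproducible;
- pruning of val/test at 30 % identity against train.

Export is plain text: `sequences.fasta`, one TSV per record with
position, residue, binary label (`-` for masked), and full-precision
frequency (`repr` of the float, so re-import is bit-exact), plus a JSON
manifest with per-split counts, positive counts, label balance, seed,
and configuration.  Import reverses this losslessly.

## 5. Evaluation metrics

Pooled over all residues of all profiles; masked positions (label −1 or
NaN score) are excluded.

- Confusion at threshold 0.5 (score ≥ threshold ⇒ positive), F1, MCC
  (both defined as 0 when a denominator vanishes);
- ROC AUC and average precision via scikit-learn (rank-based with
  midrank ties; AP as implemented by `average_precision_score`);
- max-F1 over the inclusive grid 0.00, 0.01, …, 1.00, reporting the
  smallest threshold achieving the maximum;
- coverage filtering and per-profile Spearman correlation for
  frequency-valued predictions.

All metric implementations are tested against exhaustive brute-force
oracles (pairwise concordance for AUC, enumeration for AP and max-F1).

## 6. Synthetic crystal generator

`fixtures.generate_cluster` writes PDB files for a family of chains with
planted missing segments, high-B segments, and an optional partner chain
for interface tests.  Design choices that make ground truth *exact*
rather than approximate:

- Mutations are interior-only (≥ 3 residues from each terminus) and
  capped at 8 % of the length, so the free-end-gap global alignment is
  guaranteed to be the identity mapping and planted positions align to
  themselves.
- Member 0 receives the best resolution, so it is the representative and
  profile coordinates equal generator coordinates.
- The partner chain lies 4.5 Å from the planted interface span along a
  straight Cα trace with 3.8 Å spacing; the next-nearest cross-chain
  distance is ≈ 5.9 Å, comfortably outside the 5 Å cutoff, so the
  contact span is exact.
- Planted B-factors are validated arithmetically before writing: with
  `k` high-B residues among `n`, the normalized high value approaches
  `sqrt((n−k)/k)`; the generator requires margin (z > 3.05 planted,
  z < 2.95 background) and raises an "infeasible spec" error otherwise,
  instead of silently producing wrong ground truth.
- B-factors and occupancies are written and parsed at two decimals —
  the precision of PDB fixed columns — which also removes float32 noise
  from the underlying reader.

What the generator does **not** emulate: real electron-density
heterogeneity, TLS/anisotropic B-factor models, alternate conformations
beyond simple altloc selection, non-identity alignments between family
members (insertions/deletions), crystal-packing geometry, or realistic
side-chain packing (chains are Cα traces on a line).  It is a substrate
for verifying the bookkeeping of the pipeline, not a physical simulator.

`fixtures.generate_predictions` draws positive scores from Beta(t, 1)
and negatives from Beta(1, t), where `t` solves the closed form
`AUC(t) = 1 − Γ(t+1)² / Γ(2t+1)` for the requested AUC (Brent's
method); a target of exactly 1.0 uses disjoint uniform supports.  At
10 000 residues the measured AUC is within 0.02 of the target.

## 7. Open design decisions and limitations

- Identity over the *shorter* sequence makes a short fragment cluster
  with its full-length parent; with coverage thresholds this matches
  common practice, but an identity-over-alignment-length convention
  would give different borderline clusters.
- Greedy clustering is order-dependent; longest-first with
  deterministic tie-breaking makes it reproducible but not optimal.
- ASA uses Cα-only or all-atom input as given; for Cα traces the
  absolute areas are not physical, only differences (ΔASA) are used for
  decisions.
- The 5 Å Cα–Cα contact criterion misses side-chain-mediated contacts
  between residues whose Cα atoms are far apart.
- REMARK 465 parsing covers the standard fixed-column layout; exotic
  insertion-code or model-number variants fall back to
  sequence-numbering inference.
- Problem sizes used in validation (this package's own choice): 1000
  random chains for normalization, 100 random two-chain systems for
  contacts, 50 generated families for recovery, 1000 records for
  splits, 10 000 residues for AUC calibration.
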