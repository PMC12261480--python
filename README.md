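# softdis

Soft-disorder annotation of protein crystal structures, with dataset
construction and predictor evaluation.

## The scientific problem

A protein crystal gives one static snapshot of a molecule that is, in
solution, mobile.  When the same sequence has been crystallized many
times, regions of conditional flexibility reveal themselves by being
resolved in some crystals and not others, or by carrying anomalously
high atomic displacement (B-) factors.  We call a residue **soft** in a
given chain if it is either

- **missing** — present in the SEQRES construct but absent from the
  ATOM coordinates (unresolved density), or
- **flexible** — its normalized Cα B-factor exceeds a hard threshold,

  `b_i = (B_i − mean(B)) / std(B) > 3`

  where the mean and (population) standard deviation are taken over the
  Cα atoms of that chain.

Aggregating over all chains of a sequence family yields a per-position
**soft-disorder frequency**: in what fraction of independent crystals
was position *i* soft?  Positions missing in *every* aligned chain are
not soft but **intrinsically disordered (ID)** and are masked — there is
no structural evidence either way.  This yields, per position, a
category label:

| category | meaning |
|---|---|
| `SD` | flexible (high-B) in at least one chain, never fully missing |
| `SD,DtO` | missing in some chains and ordered in others (disorder-to-order) |
| `ID` | missing in all aligned chains (masked) |
| `none` | never soft |
| `unaligned` | no chain aligned at this position |

The package also annotates **interfaces** (Cα–Cα protein contacts within
5 Å across chains; solvent-accessibility loss `ΔASA > 0.01 Å²` against
nucleic-acid partners), because soft residues are strongly enriched at
crystal and biological contacts.

## What the package does

- `structure_io` — parse PDB/mmCIF with `gemmi`, recover missing
  residues from REMARK 465 / SEQRES, select altlocs by occupancy, pick a
  best-resolution representative, and write valid PDB files back.
- `seq_cluster` — global pairwise alignment (BLOSUM62, gap open 11 /
  extend 1, free end gaps) with identity over the shorter sequence;
  greedy longest-first clustering at 90 % identity / 90 % coverage;
  leakage pruning against a reference set.
- `disorder` — B-factor normalization, per-chain soft annotation, and
  aggregation of a cluster into a `ClusterProfile` (frequencies,
  categories, interface counts).
- `interfaces` — KD-tree protein contacts; deterministic Shrake–Rupley
  solvent-accessible surface area on a 1024-point Fibonacci sphere
  lattice with NACCESS radii and a 1.4 Å probe; nucleic interfaces by
  ΔASA on complexation.
- `dataset` — profiles → per-residue labeled records, 20–2048 length
  filter, 50 %-identity redundancy reduction, deterministic 70/10/20
  splits by largest-remainder rounding, pruning of val/test above 30 %
  identity to train, text export (FASTA + per-residue TSV + JSON
  manifest) and lossless re-import.
- `metrics` — pooled per-residue evaluation: confusion counts, F1, MCC,
  ROC AUC, average precision, max-F1 over a 0.01 threshold grid,
  coverage filtering, per-profile Spearman on frequency profiles.
- `fixtures` — synthetic crystal-family generator with planted missing /
  high-B / interface segments and exact ground truth, plus score
  generators calibrated analytically to any target ROC AUC via Beta
  distributions.

## Worked example

`examples/01_annotate_crystals.py` generates four crystal structures of
one 40-residue sequence with planted defects, then rebuilds the
soft-disorder profile from the written PDB files:

```text
wrote 4 PDB entries for one sequence family
representative chain: ('ex10', 'A')
pos  n_aligned  n_missing  n_soft  freq_soft  category
  9          4          0       0      0.00  none
 10          4          2       2      0.50  SD,DtO
 11          4          2       2      0.50  SD,DtO
 12          4          2       2      0.50  SD,DtO
 13          4          0       0      0.00  none
 ...
 25          4          4       4        -    ID
 26          4          4       4        -    ID
 ...
 30          4          0       1      0.25  SD
 31          4          0       1      0.25  SD
```

Residues 10–12 were planted missing in two of four crystals
(`freq_soft = 0.50`, disorder-to-order), 25–26 missing in all four
(masked `ID`), and 30–31 high-B in one (`freq_soft = 0.25`).

`examples/04_evaluate_predictions.py` scores synthetic predictions
calibrated to ROC AUC 0.8 against 3 900 labeled residues:

```text
profiles: 20, scored residues: 3900
confusion at 0.5: tp=839 fp=785 fn=313 tn=1963
f1                0.6045
mcc               0.4096
roc_auc           0.7992
pr_auc            0.6512
max_f1            0.6086
max_f1_threshold  0.4700
```

The other examples cover interface/ASA annotation
(`02_interfaces.py`) and dataset construction with splits and a
round-trip export (`03_build_dataset.py`).

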