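# shapecov

Covariation analysis between transcription-factor (TF) protein sequences and
the nucleotide sequence **and 3D shape** of their DNA binding sites.

TFs recognize their sites through two complementary mechanisms: *base
readout* (direct contacts to base-pair chemical groups, chiefly in the major
groove) and *shape readout* (recognition of sequence-dependent DNA
structure, e.g. minor-groove geometry and its electrostatic consequences).
For homeodomains — ~60-residue domains whose recognition helix enters the
major groove while the flexible N-terminal tail probes the minor groove —
this package quantifies, from high-throughput binding data, how much of the
family's binding-specificity variation travels through each channel, and
which residues covary with minor-groove geometry.

## What it computes

Given an aligned protein family and per-protein binding-site data (8-mer
E-score tables from universal protein-binding microarrays, or pre-aligned
fixed-width sites):

1. **Motifs** — 8-mers with E-score ≥ 0.45 are aligned to the degenerate
   core consensus NNA(Y/K)N on both strands and summarized as position
   frequency matrices (PFMs). DNA-sequence similarity between proteins *i*
   and *j* is the Pearson correlation *r*(PFMᵢ, PFMⱼ) of the flattened
   matrices.
2. **Shape** — four structural features are predicted from a pentamer
   lookup table (512 pentanucleotides unique up to reverse complement):
   minor groove width (MGW, Å) and propeller twist (ProT, °) per base pair,
   Roll and helix twist (HelT, °) per base-pair step. Per protein, features
   are averaged over its aligned sites into feature vectors **v**; shape
   similarity is −‖**v**ᵢ − **v**ⱼ‖₂ (0 = identical shape).
3. **Protein similarity** — BLOSUM45 score sums over MSA columns (gaps
   skipped pairwise), over the full domain or restricted to the N-terminal
   tail (residues 1–9) or recognition helix (residues 47–55).
4. **Covariation** — the Pearson correlation between the upper triangles of
   the protein-similarity matrix and each DNA similarity matrix, with an
   empirical null from 1000 shuffles of the label-to-sequence assignment and
   a PFM-score-binned control; and per (protein column *c*, DNA position
   *p*):
   - the upper-tail cumulative hypergeometric p-value
     P(K ≥ k) with N proteins, *s* carrying a basic residue (R/K/H) at *c*,
     *m* showing a narrow minor groove (mean MGW ≤ 5.12 Å) at *p*, and *k*
     the overlap;
   - the mutual information
     MI = Σ p(m,s) log₂ [p(m,s)/(p(m)p(s))] between residue identity at *c*
     and the binary narrow/not-narrow call at *p*.
5. **Affinity models** — per protein, E-scores of all 8-mers are predicted
   by multiple linear regression with repeated 10-fold cross-validation from
   sequence features, sequence + shape features, and sequence +
   row-shuffled shape (a degrees-of-freedom control); accuracy is reported
   as R² (squared Pearson correlation between predicted and observed
   E-scores) and ROC AUC for detecting bound (E-score ≥ 0.45) 8-mers.

A first-class synthetic-data generator (`shapecov.simulate`) produces
cohorts with *planted* covariation — a basic residue at one tail column
whose carriers prefer sites with a narrower minor groove at chosen
positions — so every statistic can be validated by parameter recovery and
null control.

## Worked example

Generate a synthetic cohort of 60 proteins with a planted arginine column
(residue 5 of the tail) whose carriers prefer a ~0.5 Å narrower minor
groove at binding-site positions 4–5, then run the covariation analysis:

```
$ shapecov simulate --seed 11 --out-dir demo/data
wrote synthetic cohort (60 proteins) to demo/data

$ shapecov covary --data-dir demo/data --out-dir demo/out --seed 11
PCC(protein, dna_pfm_pcc) = +0.310 (p = 9.93e-41)
PCC(protein, shape_mgw) = +0.613 (p = 3.75e-183)
PCC(protein, shape_prot) = +0.392 (p = 4.72e-66)
PCC(protein, shape_roll) = +0.423 (p = 1.30e-77)
PCC(protein, shape_helt) = +0.381 (p = 3.99e-62)
```

Each line is the matrix-level correlation between pairwise protein
similarity and one pairwise DNA similarity over the 1770 protein pairs: the
planted cohort covaries most strongly through minor-groove shape (+0.613),
and `demo/out/manifest.json` records that the shuffle null is centred at
−0.001 with a 99th percentile of +0.079 — the observed correlation is far
outside it. The manifest also reports the argmax of the hypergeometric and
mutual-information maps at protein position 5 / DNA position 5 (1-based),
i.e. the analysis re-identifies the planted residue column and affected
site position from the binding data alone. Per-statistic matrices are
written as TSV (`map_hypergeom_neglog10p.tsv`, `map_mutual_information.tsv`,
`similarity_*.tsv`, `shape_profiles.tsv`, `pfms.meme`).

The same stages are importable as a library (`shapecov.analyze_cohort`), and
`shapecov affinity` runs the cross-validated E-score regression for one
protein.

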