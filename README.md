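# contactbench

Benchmarking evolutionary residue–residue contact predictors against
structure-derived CA–CA contact maps, across a ladder of distance
cutoffs.

## The problem

Several families of methods predict intra-domain residue contacts from
evolutionary data: correlated-mutation / coevolution analysis (CMA),
conservation bands over per-column sequence variability and Shannon
entropy (VRN), bands over compression-based Kolmogorov complexity
(KOL), residue-type-pair likelihood matrices derived from the PDB
(SVB), and pair-to-pair substitution scoring (P2P). They are usually
scored against a contact map at one arbitrary cutoff — but "contact"
definitions in the literature range from 3.7 Å hydrogen bonds to 12 Å
long-range couplings. This package asks the sharper question: **at
which distance does each method's prediction quality peak?** That
cutoff is the method's *characteristic contact distance*, and methods
turn out to differ in it — so they are best combined, not averaged.

For residue pairs evaluated over the full universe of n(n−1)/2
unordered pairs, with TP/FP/FN/TN counted against the contact map at
cutoff *c*:

```
MCC(c)   = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
ACCY(c)  = (TN − TP) / (TP+FP+FN+TN)      (reported-table convention;
                                           (TP+TN)/total also computed)
PREC(c)  = TP / (TP+FP)
SENSY(c) = TP / (TP+FN)
```

The characteristic distance is argmax over the cutoff ladder
{3.8, 4.0, 4.5, 5.0, 5.5, 6.0, 8, 10, 12, 14, 16, 18, 20} Å of MCC(c),
after subtracting the mean metric of equally sized uniformly random
prediction sets (the RND correction). A cross-method PCA of the
corrected metric profiles shows which methods share underlying signal
and how each relates to the contact scale.

The package is aimed at structural bioinformaticians evaluating or
combining contact predictors. It ships the published benchmark grid for
the α-lactalbumin domain (PDB 1a4v: 45 rows of confusion counts, five
methods × nine cutoffs) as a regression anchor, and a synthetic
generator producing coupled (structure, alignment) fixtures with known
ground truth so the whole pipeline is testable without downloads.

## Worked example

`examples/04_calibration_and_scan.py` runs the full range-predictor
workflow on a synthetic protein whose contacts were planted at 8 Å:

```
calibrated ENT band center: 0.25 +/- 0.25 bits
per-cutoff optima agree: True  ({'6A': 0.25, '10A': 0.25})
prediction: 561 pairs from range 0.25±0.25, 34 positions

cutoff (A)    MCC   MCC_corr
      3.8   0.162     0.163
      ...
      6.0   0.231     0.228
      8.0   0.275     0.276
     10.0   0.256     0.255
     12.0   0.185     0.181
      ...
     20.0   0.000     0.000

characteristic distance: 8 A (generator truth: 8 A)
```

Reading this: calibration scanned candidate entropy-band centers and
found 0.25 bits optimal at both 6 Å and 10 Å (the optima agreeing is
itself a result — the useful conservation band does not depend on the
contact definition used to find it). The 34 positions in that band give
C(34,2) = 561 candidate pairs; their MCC against the contact map peaks
at 8 Å — exactly the distance at which the generator planted its
contacts — and the random-baseline-corrected MCC (~0.28) shows the
signal is far above chance.

The other examples cover column scores (`01`), contact-map nestedness
(`02`), recomputing the published benchmark and its peak cutoffs
(`03`), the method PCA (`05`), and the one-shot YAML-driven pipeline
(`06`). A thin CLI mirrors the stages:

```bash
contactbench synth --n-residues 60 --n-sequences 100 --seed 5 --out-prefix demo
contactbench stats demo.fasta --out scores.tsv
contactbench evaluate --msa demo.fasta --pdb demo.pdb --score ent \
    --center 0.25 --half-width 0.25 --seed 1 --out metrics.tsv
contactbench peaks metrics.tsv
contactbench run-all run.yaml
```

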