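# ppisites

Residue-pair prediction of protein–protein interaction (PPI) sites from
bound dimer structures, for structural bioinformaticians who work with
docking-benchmark-style complexes.

Given a two-chain complex, the package:

1. **labels every cross-chain residue pair** by the distance rule — a pair
   (r, l) interacts iff the minimum Euclidean distance over its heavy atoms
   is ≤ 6 Å (inclusive);
2. **purifies the positive class with binding-propensity statistics.** With
   N_i residues of type *i* among N surface residues and M_ij interface
   contacts between types *i* and *j*:

       AR_i    = N_i / N            (background surface abundance)
       AIR_ij  = M_ij / M_i         (conditional partner frequency)
       RAIR_ij = AIR_ij / AR_j      (partner enrichment over background)

   a type pair with RAIR ≥ 1 has *high binding propensity*; positive training
   pairs whose type pair is not high-propensity are treated as likely
   bystanders and dropped. A reference 20×20 RAIR matrix estimated on a
   curated docking-benchmark dimer set is packaged (221 of its 400 ordered
   cells are ≥ 1, and ten partner residues — L, I, V, R, H, C, M, Y, W, F —
   are high-propensity for a majority of rows);
3. **encodes each residue as 217 features**: 20-dim identity one-hot, a
   length-3 window of PSI-BLAST profile rows (logistic-squashed PSSM ∥ PSFM,
   3×40 = 120), 24 physicochemical properties as 3-group one-hots (72), and
   five structure features [ASA, relative ASA, protrusion CX, depth DPX,
   hydrophobicity]. A residue pair is the 2×217×1 stack of its two vectors;
4. **classifies pairs with a small convolutional network** (3×3/32, 3×3/64,
   1×3/128 conv + max-pool stages, a 1024-unit softplus layer with dropout,
   2-way softmax; Adam with decaying learning rate), exposed as a
   scikit-learn estimator (`PairCNNClassifier`);
5. **evaluates by pooled ROC AUC and RFPP** under leave-one-complex-out or
   k-fold (split by complex) cross-validation: training sets are balanced by
   undersampling negatives, test sets are the full imbalanced pair lists.
   RFPP(p) is the smallest rank q such that p% of complexes have a true
   interacting pair among their top-q predictions.

Solvent-accessible surface area is computed natively (Shrake–Rupley sphere
sampling, probe 1.4 Å); externally computed per-residue ASA tables can be
injected instead. A synthetic-dimer generator (`ppisites.synth`) builds
complexes with planted, margin-verified contact interfaces, plausible profile
files, and controllable contact-type enrichment and feature signal, so the
entire pipeline is testable with no downloads.

## Worked example

```python
from ppisites import SynthSpec, make_dimer, parse_structure, label_pairs
from ppisites.propensity import (classify_high_propensity,
                                 reference_propensity_matrix, filter_positives)

spec = SynthSpec(n_complexes=1, chain_lengths=(30, 30), interface_size=5, seed=0)
pdb_text, truth = make_dimer(spec, 0)

s = parse_structure(pdb_text, ("A", "B"), "SYN0000")
pairs = label_pairs(s)
pos = [p for p in pairs if p.y == 1]
print(f"pairs: {len(pairs)}, interacting: {len(pos)}")

high = classify_high_propensity(reference_propensity_matrix())
kept = [p for p in filter_positives(pairs, high) if p.y == 1]
print(f"high-propensity positives kept: {len(kept)}")
for p in pos:
    tag = "kept" if p in kept else "dropped"
    print(f"  {p.aa_r}{p.r_key[1]+1} - {p.aa_l}{p.l_key[1]+1}  "
          f"d={p.min_atom_distance:.2f} A  {tag}")
```

prints

```
pairs: 900, interacting: 5
high-propensity positives kept: 4
  N8 - N22  d=3.40 A  dropped
  M10 - K15  d=3.40 A  kept
  Y15 - L18  d=3.40 A  kept
  H18 - T26  d=3.40 A  kept
  V23 - R19  d=3.40 A  kept
```

The 30×30-residue dimer yields 900 cross-chain pairs of which the 5 planted
contacts are recovered; the N–N contact is dropped by the propensity filter
because asparagine–asparagine enrichment is below 1 in the reference matrix
(RAIR_NN = 0.54), while the other four type pairs are high-propensity.

A full end-to-end benchmark (featurize → balance → train CNN → leave-one-
complex-out evaluation) runs from the shell:

```
ppisites loco-benchmark --n-complexes 10 --signal 6.0 --seed 0
```

Other subcommands: `ppisites surface`, `ppisites pairs`,
`ppisites propensity-filter`, `ppisites evaluate`, `ppisites synth-make`.

## Layout

```
src/ppisites/
  structure.py    PDB parsing, Shrake-Rupley ASA, surface residues
  interface.py    cross-chain pair enumeration, 6 A labelling
  propensity.py   AR / AIR / RAIR statistics, tendency, positive filtering
  profiles.py     PSI-BLAST ASCII profile reader/writer
  features.py     217-dim encoding and pair assembly
  datasets.py     sample selection and balanced undersampling
  nn.py, cnn.py   numpy conv-net layers and the sklearn estimator
  evaluation.py   AUC, RFPP, confusion counts, LOCO / k-fold drivers
  synth.py        synthetic dimers, profiles, planted-signal benchmarks
  pipeline.py     end-to-end benchmark drivers
  data/           packaged reference tables (TSV)
```

See `docs/methods.md` for the model, parameter choices, and limitations.
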