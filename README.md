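# proligand

Template-guided assembly of protein–ligand complex models from cryo-EM
backbone traces, with Q-score map–model validation.

## The problem

Deep-learning map tracers (e.g. DeepTracer) turn a high-resolution cryo-EM
density map into a backbone-only protein model (N, CA, C, O atoms) within
minutes, but produce no side chains and no ligands. A previously solved
reference (template) structure of the same protein carries full atoms and
bound ligands, but reflects a prior conformation. `proligand` combines the
two and scores the result:

1. **Superpose** — chains are paired by global sequence alignment
   (Needleman–Wunsch, BLOSUM62, gap open −11 / extend −1) and the predicted
   model is placed in the reference frame with a single least-squares rigid
   fit (Kabsch) over all matched CA pairs.
2. **Merge** — for every reference residue, if the nearest predicted CA (over
   *all* predicted chains) lies within a per-chain distance threshold
   *d* < *t* (default *t* = 1 Å), each backbone atom present in both residues
   is moved to the midpoint (x_ref + x_pred)/2; otherwise the reference
   coordinates are kept. The merge report tallies per-chain counts and
   percentages of averaged residues.
3. **Graft ligands** — hetero residues of the reference that pass the ligand
   rules (not water, not a standard amino acid/nucleotide, ions optional) are
   appended to the merged model with coordinates bit-identical to the
   reference.
4. **Score** (optional) — given an MRC/CCP4 map, each ligand atom gets a
   Q-score: the Pearson correlation between shell-averaged map values around
   the atom and a reference Gaussian
   g(d) = low + (high − low)·exp(−½(d/σ)²), σ = 0.6 Å by default. Per-target
   Q-scores of competing models standardize to Z-scores (sample sd) and sum
   into a cumulative leaderboard score.

## Worked example

Generate a synthetic two-chain helical reference with two PTQ-like ligands, a
perturbed backbone-only "prediction" (0.1 Å noise, 20 % of residues displaced
3 Å, a known rigid motion), and an ideal density map; then run the pipeline:

```python
import json
from proligand import (FixtureSpec, make_reference, make_predicted,
                       simulate_map, write_pdb, write_mrc)

spec = FixtureSpec(n_chains=2, residues_per_chain=50, noise_sd=0.1,
                   fraction_displaced=0.2, rigid_rotation_axis=(0.3, 1.0, -0.5),
                   rigid_rotation_deg=25.0, rigid_translation=(2.0, -6.0, 4.0),
                   ligand_codes=("PTQ", "PTQ"), seed=17)
ref = make_reference(spec)
pred, truth = make_predicted(ref, spec)
open("ref.pdb", "w").write(write_pdb(ref))
open("pred.pdb", "w").write(write_pdb(pred))
write_mrc(simulate_map(ref, voxel=0.5, sigma_atom=0.6), "map.mrc")
json.dump({"reference": "ref.pdb", "predicted": "pred.pdb",
           "density_map": "map.mrc", "outdir": "out", "seed": 7},
          open("cfg.json", "w"))
```

```text
$ proligand run --config cfg.json
complex: out/complex.pdb
report: out/merge_report.tsv (overall 80.00%)
qscores: out/qscores.tsv (ligand mean q 0.9908)

$ cat out/merge_report.tsv
chain	total	averaged	percent
A	50	38	76.0
B	50	42	84.0
#overall			80.00
```

80 % of residues averaged is exactly the non-displaced fraction of the
fixture (the 20 displaced residues correctly kept their reference
coordinates), and the ligand mean Q-score of 0.99 reflects that the map was
simulated from the same Gaussian the score assumes — a well-resolved ligand.

Per-stage subcommands (`merge`, `graft-ligands`, `qscore`, `rank`,
`simulate`) expose the same operations individually; see `proligand --help`.

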