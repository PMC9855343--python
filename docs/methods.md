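# Methods

## Model and procedure

`proligand` implements a template-guided reconstruction of protein–ligand
complexes. The inputs are a full-atom reference (template) structure with
ligands and a backbone-only predicted structure (N, CA, C, O), typically
traced from a cryo-EM density map. The reasoning is Bayesian in spirit: the
reference is the prior conformation, the map-derived backbone is the
likelihood term, and the merged model is the posterior compromise — taken
atom-by-atom where the two agree, and from the reference where they do not.

### Superposition

Chain correspondence is a greedy one-to-one assignment maximizing global
Needleman–Wunsch alignment score (BLOSUM62, gap open −11 / extend −1,
Biopython `PairwiseAligner`); a pair is only accepted at ≥ 30 % sequence
identity over aligned columns, and residues outside the 20 standard amino
acids map to `X` (selenomethionine maps to `M`). Residue pairs are the
aligned columns whose residues both carry a CA atom. One global Kabsch fit
(SVD of the CA cross-covariance, reflection branch corrected to det = +1)
places the whole predicted complex in the reference frame — a single fit,
not per-chain fits, because the merge step decides agreement per residue
anyway. No outlier pruning is done by default: the merge threshold already
rejects discordant residues. An optional pruning mode (drop pairs > 2 Å
after fitting, ≤ 5 rounds) is available for badly contaminated matches.

### Backbone averaging

For each reference polymer residue, the nearest predicted CA is sought over
*all* predicted chains (ties broken toward the lowest (chain, residue
number) key). If its distance is strictly below the chain's threshold —
default 1 Å, overridable per chain, e.g. 0.3 Å for an unusually mobile chain
and 0.5 Å elsewhere — each of N, CA, C, O present in *both* residues moves to
the arithmetic midpoint; all other atoms (side chains, OXT, hydrogens) keep
reference coordinates, as do whole residues that fail the test. Boundary
equality (d == t) keeps the reference. A predicted residue may serve as
nearest neighbour to several reference residues; the procedure imposes no
one-to-one constraint. Occupancies and B-factors are always copied from the
reference. Hetero residues are never averaged and are not carried into the
merged structure — the ligand-transfer stage re-appends them from the
reference, which also makes re-running the transfer detectably idempotent.

The merge report gives, per chain, total and averaged polymer-residue counts
and the percentage rounded to 1 decimal; the per-target overall figure is
the mean of those (rounded) per-chain percentages, reported to 2 decimals.
Using the printed per-chain values, rather than unrounded ratios, is what
makes the overall figure reproducible from a published per-chain table
alone.

### Ligand transfer

A residue is a ligand iff it is a HETATM residue, not water (HOH/WAT,
unless waters are requested), not a standard amino acid or nucleotide
(MSE counts as polymer), and passes the explicit include/exclude sets;
single-atom hetero residues (metal ions) are included by default. This rule
set replaces a chemical-component-dictionary lookup; the policy flags make
the borderline cases (waters, ions) explicit choices rather than guesses.
Transferred coordinates are bit-identical to the reference — no transform is
applied, because the superposition moved the *predicted* model into the
reference frame, never the reverse.

### Q-score

The Q-score of an atom is the Pearson correlation between u, the map values
sampled around the atom, and v, the values of a reference Gaussian — the
profile the map would show if the atom were perfectly resolved:

    g(d) = low + (high − low) · exp(−½ (d/σ)²)

Sampling uses concentric shells at radii 0, 0.1, …, 2.0 Å with 8 points per
shell on a Fibonacci lattice, each shell independently rotated by a seeded
random rotation; shell values are averaged before correlating (length-21
vectors), which suppresses orientation noise. Points outside the map are
dropped, and a radius with no in-bounds points is dropped from both vectors
(zero-filling would bias q near map edges); fewer than 3 usable radii makes
the atom unscorable. Defaults: σ = 0.6 Å, high = map mean + 10 sd, low = map
mean − 1 sd. These are conventions of the Q-score family of measures, not
derivable from first principles, and all four are configurable; agreement
with any particular external implementation therefore depends on matching
its settings. Selection-level scores are unweighted means over scorable
atoms.

Z-scores standardize one target's per-group Q-scores with the sample
standard deviation (ddof = 1); a zero spread yields all-zero z with a
warning rather than an error. Cumulative Z sums across targets, with
missing entries contributing 0.

## File handling

PDB parsing is delegated to gemmi behind a light fixed-column validation
pass (gemmi silently coerces malformed coordinate fields to 0, so numeric
fields are checked first and errors name the line). Only the first MODEL is
read; alternate locations resolve to the highest-occupancy conformer, ties
to the first in file; insertion codes are preserved verbatim. Writing is an
in-package fixed-column formatter (3-decimal coordinates, TER after the
polymer part of each chain, END last); a test cross-checks its output
against gemmi's reader. MRC/CCP4 maps go through `gemmi.Ccp4Map` with axis
order normalized to (x, y, z) on read; grids are held as float64 in memory
so that affine intensity transforms are exact, narrowing to float32 (mode 2)
only on write. Interpolation is trilinear (`scipy` RegularGridInterpolator).

## Synthetic fixtures

The generator emulates the pipeline's two inputs with analytic ground truth.
The reference is an ideal α-helical poly-alanine backbone — rise 1.5 Å, 100°
turn, 2.3 Å radius, giving consecutive CA–CA distances of ≈ 3.83 Å — with
N/C/O at fixed offsets from CA in the local helix frame, and optional
5-atom hetero "ligand" clusters placed 5 Å radially out from a chain's last
CA. The prediction is the polymer backbone with isotropic Gaussian noise
(default 0.1 Å), a chosen fraction of residues displaced 3 Å along the
outward radial direction (outward, not random, so a displaced CA is ≥ ~3 Å
from *every* reference CA and the threshold semantics stay unambiguous), and
a known rigid transform applied last. Density maps are sums of atom-centred
isotropic Gaussians with a 5σ support cutoff on a regular grid (default
0.4–0.5 Å voxels).

What the fixtures do not emulate: real protein folds and side chains,
sequence diversity beyond poly-alanine (chain matching is therefore
exercised with artificially diversified sequences in tests), experimental
map artefacts (anisotropy, B-factor blurring, solvent noise, masking), and
tracer-specific error modes (chain breaks, register shifts). Passing tests
show the geometry, bookkeeping and scoring are correct, not that the
pipeline's thresholds are optimal for any particular real map.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 non-collinear pairs (rank check at 1e-8); near-planar
  sets still return a proper rotation via the sign-corrected SVD branch.
- Nearest-CA ties resolve deterministically to the lowest (chain, number)
  key; all generators and shell sampling are seeded, and pipeline logs omit
  timestamps, so identical config + seed gives byte-identical outputs.
- Thresholds must be strictly positive; a threshold of 1e-9 reproduces the
  reference exactly (0 % averaged), and identical inputs give 100 %.
- A flat sample vector (e.g. constant map) has no defined correlation; the
  atom scores 0 with a warning rather than propagating NaN.
- Problem sizes used in tests and the acceptance script (2 × 50-residue
  chains, 10–50-point Kabsch sets with a 10,000-sample Monte-Carlo optimality
  oracle, 8-residue ligand maps at 0.4 Å voxels, 17-group Z-tables) keep
  the whole suite in the low seconds while leaving the measured properties
  (exact set recovery, < 1° transform recovery, q ≥ 0.98 on ideal maps)
  comfortably away from their tolerances.

## Known limitations

Backbone averaging can produce locally strained geometry (bond lengths and
angles are not restrained), and the package deliberately stops before
side-chain packing, energy refinement and map-space rigid-body optimization
— those are established external tools' jobs, reachable through the
per-stage outputs. Q-score parameter defaults are conventions; absolute
values on real maps depend on them, while the properties tested here
(boundedness, affine invariance, ideal-map recovery, anti-correlation) do
not. mmCIF input, multi-model ensembles and non-orthogonal map cells are
out of scope.
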