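# chidist

Side-chain χ-angle distribution functions for protein surfaces: build them,
compare them, and find the grid resolution at which bound and unbound
conformations become indistinguishable.

## The problem

When two proteins associate, their interface side chains rearrange.  How
large are those rearrangements, and how do they compare with the ordinary
conformational variability of the rest of the surface?  One way to answer
is distributional: for each amino-acid type, collect the side-chain
dihedral (χ) angle vectors of many residues — interface and non-interface,
in bound and unbound structures — estimate the *dihedral-angle distribution
function* (DADF) of each pool on a grid over χ space, and measure how
similar the distributions are as a function of the grid resolution.

`chidist` implements that analysis end to end for structural
bioinformaticians and docking-method developers:

- a minimal PDB reader and per-residue Shrake–Rupley solvent accessibility;
- interface classification (surface residue: relative SASA ≥ 25% in bound
  and unbound state; interface residue: loses > 1 Å² SASA upon binding);
- bound↔unbound residue mapping by global sequence alignment;
- χ-angle computation with symmetry folding (the last χ of Phe, Tyr, Asp,
  Glu lives on [0°, 180°) because the terminal group is two-fold symmetric);
- n-dimensional circular histograms (DADFs) with arbitrary split origins;
- similarity statistics with an offset-averaging protocol, and a synthetic
  rotamer-mixture generator so everything runs without external downloads.

## The statistics

Two DADFs X and Y built on the same m-cell grid are compared by the Pearson
correlation over cells,

    r = Σᵢ (Xᵢ − X̄)(Yᵢ − Ȳ) / sqrt( Σᵢ (Xᵢ − X̄)² · Σᵢ (Yᵢ − Ȳ)² ),

with X̄ = (1/m) Σᵢ Xᵢ, and by the Manhattan distance

    d(X, Y) = ½ Σᵢ |Xᵢ − Yᵢ|  ∈ [0, 1],

which is 0 for identical distributions and 1 for disjoint ones.  Both
depend on where the grid origin falls, so the estimator of record repeats
the calculation (default 100×) with random split origins shared by X and Y
and reports means and standard deviations.  The *critical spacing* of a
spacing scan is the smallest spacing at which the mean correlation reaches
0.7 — the resolution at which two pools stop being distinguishable at a
high level.

## Worked example

Compare an "unbound" pool of 2000 synthetic Ser χ1 angles with a paired
"bound" pool in which 2% of side chains flip to another rotamer and all of
them pick up 10° of intra-rotamer readjustment:

```python
import numpy as np
import chidist as cd

spec = cd.RotamerMixtureSpec("SER", jitter_sd=10.0)
rng = np.random.default_rng(1)
unbound = cd.sample_pool(spec, 2000, rng)
bound = cd.perturb_paired(
    unbound,
    cd.PairedPoolSpec(base=spec, flip_prob=0.02, jitter_sd=10.0, n=2000),
    rng)

model = cd.DadfComparison(unbound.angles, bound.angles, "SER", spacing=30.0,
                          category_pair="interface_bound_vs_unbound")
result = model.fit(rng=0)
print(result.summary())
```

```
DADF comparison (offset-averaged)
=============================================
residue type                SER
category pair               interface_bound_vs_unbound
grid spacing (deg)          30
grid cells m                12
samples (X / Y)             2000 / 2000
repeats (undefined r)       100 (0)
---------------------------------------------
mean correlation r          0.9899 +/- 0.0053
mean Manhattan distance d   0.1014 +/- 0.0451
p-value (t, df=m-2)         7.95e-10
=============================================
```

Despite the perturbation, the two 30°-resolution distributions correlate at
0.99 (highly significant over the 12 cells) and differ by only ~10% of
probability mass — rotamer flips are rare, and 10° readjustments mostly
stay inside a 30° cell.

The same machinery runs from the shell.  A full analysis from a manifest of
bound/unbound PDB files:

```sh
chidist run manifest.tsv --seed 3 --out results/
```

writes the classified angle table, per-residue-type counts, the comparison
table (four category pairs × spacing scan) and the critical-spacing table.
`chidist synth`, `chidist angles`, `chidist compare` and `chidist counts`
expose the individual stages.

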