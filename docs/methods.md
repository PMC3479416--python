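# Methods

This note records the models, numerical choices and limitations behind
`chidist`, in the order the pipeline uses them.

## Structure model and parsing

Only fixed-column `ATOM` records are read: HETATM groups, waters and
hydrogens are excluded, and only the first `MODEL` of multi-model files is
used.  Alternate locations are resolved per atom name to the
highest-occupancy conformer, with ties broken by file order — a
deterministic, conventional rule.  Non-standard residues are retained in
the structure model (they occlude surface like any other atoms) but are
excluded from classification and from the angle pools, which cover the 18
standard χ-bearing amino-acid types.  Hydrogens are ignored throughout:
SASA and torsions use heavy atoms only, because crystal structures at
typical resolution rarely resolve them.

## Solvent accessibility

Per-atom SASA uses the Shrake–Rupley construction: `n_points`
quasi-uniform test points (golden-spiral lattice, default 960) on each
atom's probe-expanded sphere (probe 1.4 Å); a point is accessible when it
lies outside every other atom's expanded sphere, and

    SASA_i = (accessible / n_points) · 4π (r_i + probe)².

Each atom's point lattice is given a deterministic orientation derived from
a hash of its coordinates.  With one shared orientation, per-atom
quadrature errors are mutually correlated and add up coherently in totals
(rigid-rotation discrepancies up to ~0.7% of the total were observed on
toy structures); with per-atom orientations they decorrelate and totals are
rotation-stable to ~0.1% at 960 points.  Because the orientation is keyed
on coordinates, an atom has the *identical* point set in a complex and in
a monomer extracted from it, so the SASA lost upon binding is exactly
non-negative (occlusion can only bury points); negative ΔSASA within 1e-6
Å² is clamped to zero as floating-point noise.

Van der Waals radii follow the NACCESS tradition (N 1.65, O 1.40, S 1.85,
sp² C 1.76, sp³ C 1.87 Å), shipped in `data/radii.json`; unknown atoms fall
back to their element default with a warning.  Relative SASA divides the
residue sum by the theoretical residue-type maxima of Tien et al. 2013
(`data/rel_sasa_max.tsv`); values slightly above 1 occur for extended
conformations and are legitimate.

## Classification

A residue is *surface* when its relative SASA is ≥ 25% in the bound
monomer and, when an unbound counterpart exists, also in the unbound
structure; it is *interface* when, additionally, it loses > 1 Å² SASA upon
binding, and *non-interface surface* otherwise.  Two conventions matter:

- Bound-state exposure is computed on the monomer **extracted from the
  complex coordinates**, not on the residue inside the complex — otherwise
  every interface residue would fail the 25% rule by construction.
- Proteins with no unbound counterpart are classified from the bound state
  alone; their residues enter only the bound pools.

ΔSASA is always evaluated on the bound coordinates; a mapped unbound
residue inherits its partner's interface status.

## Residue correspondence

Bound and unbound chains are paired positionally (i-th bound chain ↔ i-th
unbound chain of a case) and their sequences aligned with a global
Needleman–Wunsch (match +1, mismatch −1, linear gap −2, traceback ties
broken diagonal > up > left).  At the > 97% identity typical of
bound/unbound pairs any reasonable scheme gives the same mapping; this one
is the simplest fully deterministic choice.  Aligned but mismatched
positions are left unpaired — a substituted side chain has no comparable
dihedrals — and identity below 0.97 raises a warning without aborting.

## χ angles

χ definitions are the standard IUPAC heavy-atom quadruples (χ1 =
N–CA–CB–γ, sliding window thereafter; Arg truncated at χ4).  Torsions use
the atan2 formulation and live on [−180°, 180°); the value +180° is
normalized to −180° to keep the range half-open.  The last χ of Phe, Tyr,
Asp and Glu is folded into [0°, 180°) by the two-fold symmetry of the
terminal ring or carboxylate; no amide/imidazole flip correction is
applied to Asn/Gln/His.  A residue missing any χ-defining atom is dropped
entirely (a partial vector has no cell in an n-dimensional histogram) and
logged.

## DADFs

For a residue type with n χ angles, the grid covers each full-range
dimension's 360° circle and each folded dimension's 180° circle with one
spacing; the per-dimension cell count is ceil(width / spacing), so
non-divisor spacings (e.g. 70°) produce one narrower wrap cell rather than
losing samples.  Each dimension carries an independent *offset* (split
origin) in [0, spacing); angles are binned circularly, so an offset grid's
first boundary wraps across ±180° (or 0°/180° on folded dimensions).
Cells flatten row-major with χ1 slowest.  Empty cells are retained at
probability zero: the correlation's sums run over all m cells, which
affects the cell-mean and the variances and is therefore part of the
statistic's definition, not an implementation detail.

## Comparison protocol

The correlation r and Manhattan distance d = ½ Σ|Xᵢ − Yᵢ| are computed on
a grid shared by both DADFs (same spacing *and* offsets — cell-wise
comparison is meaningless otherwise).  Because both statistics depend on
the split origin, `DadfComparison.fit` repeats the calculation (default
100×) with fresh uniform random offsets and reports arithmetic means and
standard deviations over repeats.  Repeats in which a DADF is exactly
uniform (zero variance, r undefined) are skipped and counted, not
zero-filled, which would bias the mean; if every repeat is undefined the
fit raises.  Identical probability vectors short-circuit to r = 1.0 and
d = 0.0 exactly, a guarded degenerate-case guarantee immune to rounding in
the ratio.

Significance of the mean correlation uses t = r·sqrt((m−2)/(1−r²)) on m−2
degrees of freedom, with the cell count m as the sample size — the
correlation's observations are cells.  This is a pragmatic choice: cells
of a histogram are not independent draws, so the p-value is an ordering
device, not a calibrated error rate.

The critical spacing of a scanned series is the smallest spacing whose
mean r reaches 0.7.  The default scan is 10°–90° in 10° steps,
configurable; comparisons are run for the four category pairs (interface
bound vs unbound, non-interface bound vs unbound, non-interface vs
interface in each state) per residue type, pooling residues across all
cases.  Pools below `min_samples` (default 20) are reported as skipped:
correlations between sparse histograms are dominated by sampling noise.

Determinism: every (residue type, category pair, spacing) cell derives its
random-offset stream from the configured seed plus the cell's identity, so
output tables are byte-identical across runs and independent of iteration
order.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:
per χ dimension, angles cluster in three rotamers 120° apart (centers
−60°, 60°, 180°; 30°, 90°, 150° on folded dimensions), with wrapped-normal
intra-rotamer jitter of 10° by default — the scale of rotamer-library
spreads for χ1.  A von Mises alternative (`kappa`) is available; only the
clustered-with-tails shape matters to the tests.  Rotamer weights default
to equal thirds.  A paired ("bound") pool derives from a base ("unbound")
pool by two perturbation modes: with probability `flip_prob` a sample's
rotamer is re-drawn uniformly among the others and its angle resampled,
and wrapped-normal jitter of `jitter_sd` is always added — rare
rotamer-to-rotamer transitions plus ubiquitous local readjustment.

Two consequences of these defaults are worth knowing.  With equal rotamer
weights, uniform flips leave the *marginal* mixture unchanged, so
flip-sensitivity tests use a skewed mixture (0.6/0.25/0.15) for the effect
to be visible in distribution space.  And because the paired jitter is
*added* to the base jitter, the paired marginal is a convolution (10° base
+ 10° jitter → 14.1° spread): at 30° spacing the offset-averaged Manhattan
distance between the two marginals has a systematic floor of ≈ 0.105,
independent of sample size.  The package reports this honestly rather than
hiding it; it is the expected behavior of additive readjustment noise.

Toy coordinate models place atoms by sequential internal-coordinate (NeRF)
construction from ideal bond lengths and angles
(`data/ideal_geometry.json`, Engh & Huber-style values), with torsions set
to prescribed χ targets; prescribed angles round-trip through the torsion
code to < 1e-6°, or ~0.01° after writing to PDB's 3-decimal coordinates.
Toy multi-residue structures are rigid placements without peptide bonds —
sufficient for SASA and torsion exercises, not for backbone analysis.

What the generator does **not** emulate: backbone-dependent rotamer
frequencies, residue-type-specific rotamer populations, correlations
between χ dimensions, crystal-packing geometry, or experimental
coordinate error.  Tests passing on synthetic pools therefore validate
the statistical machinery (binning, offset averaging, the similarity
measures and their trends), not claims about any particular protein set.

## Problem sizes

The test suite and acceptance script run entirely on synthetic inputs at
desk scale: pools of 500–2000 chi vectors, 20 generator seeds where trends
are averaged, 20–100 random split origins per comparison, and toy
structures of up to ~25 residues for the geometric checks.  These sizes
give comfortably stable Monte-Carlo bands for every asserted trend.

## Known limitations

- The Shrake–Rupley implementation is numerical; it matches analytic
  isolated-sphere areas to < 1% at 960 points and an independent
  implementation (biotite) to ~1% on toy structures, but is not
  bit-compatible with Lee–Richards slice algorithms such as NACCESS's, so
  borderline residues near the 25%/1 Å² thresholds can classify
  differently than under that program.
- Relative SASA depends on the reference-maxima table; switching tables
  shifts the surface threshold's meaning.
- The p-value treats grid cells as independent observations (see above).
- mmCIF input, symmetry expansion, kernel density estimation, adaptive
  binning and rotamer-library fitting are out of scope.
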