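# Methods

## The model

`samcascade` simulates the epidermis-to-interior signalling cascade of
the *Arabidopsis* shoot apical meristem (SAM) as deterministic
reaction–diffusion ODEs on a static multicellular template. The input
is the per-cell level of functional ATML1/PDF2 protein, `[ML1p]`
(arbitrary units, a.u.); the dynamic species are miR171, *HAM* mRNA,
HAM protein, and the mRNA/protein pair of an H2B-GFP reporter of
*MIR171* promoter activity. miR171 is produced in proportion to local
`[ML1p]`, degraded at a constant per-capita rate, and exchanged between
neighbouring cells through a graph-Laplacian term `D_mir171 Δ[miR171]`
with `Δf_i = Σ_{n∼i}(f_n − f_i)`. *HAM* mRNA is produced uniformly in
every cell (`k_hrp`) and degraded through both a miR171-independent
channel (`k_hrnh`) and miRNA-guided cleavage (`k_hrnm [HAMr][miR171]`);
protein and reporter species are linear followers. The reporter has no
feedback on the cascade, and assumptions worth stating explicitly:

* the template is static — no growth, division or cell movement;
* only miR171 moves; all mRNAs and proteins are cell-autonomous;
* `[ML1p]` is a fixed input field, not a dynamic species;
* kinetics are mass-action, concentrations in a.u., time in hours.

The model's characteristic behaviour follows from the single-cell
closed form. Without diffusion, each cell settles at
`miR171* = k_mirp M / k_mirn` and
`HAMr* = k_hrp / (k_hrnm miR171* + k_hrnh)`: *HAM* mRNA is high
wherever miR171 is absent and suppressed wherever `[ML1p]` (hence
miR171) is present. Diffusion converts the epidermal miR171 source
into a declining gradient over a penetration depth of roughly
`sqrt(D_mir171 / k_mirn)` cell diameters, which produces the
apical(low)–basal(high) *HAM* pattern.

## The synthetic template

No cell-resolved SAM geometry ships with the package, so the generator
builds an idealised stand-in: spheres on concentric spherical-cap
shells under a dome. Cells are apportioned across shells in proportion
to shell area (largest-remainder rounding, so the requested count is
met exactly) and laid out on latitude rings with area-weighted per-ring
counts and golden-angle stagger plus a small seeded phase. The default
geometry (curvature radius 16, height 8, six shells spaced 2 length
a.u. apart) was fixed so that the standard configuration holds 1216
cells in proportions resembling a medium SAM dome: 390 epidermal (L1),
299 sub-epidermal (L2), 527 corpus cells. The sphere radius is uniform
up to a deterministic ±4 % jitter and is derived from the realised
packing: 0.58 × the longest edge of a Euclidean minimum spanning tree
of the centres, which guarantees a connected overlap graph with the
default overlap factor 1.0 (two cells are neighbours when their
centre distance is below the sum of their radii). Layers are read off
the construction's shell index — outermost shell L1, next L2, the rest
corpus — rather than recovered by a geometric classifier.

What the generator does *not* emulate: realistic cell-size and
cell-shape heterogeneity, anticlinal/periclinal wall anisotropy, the
exact adjacency statistics of a segmented meristem, and any growth.
Conclusions that depend only on layered topology and short-range miRNA
movement transfer to real templates; quantitative neighbour-count
statistics do not.

Input fields: wild type is 1 a.u. in every L1 cell and 0 elsewhere;
ectopic ATML1 activation uses 1.1 a.u. in L1 and 0.4 a.u. in all
deeper layers; the robustness set comprises 75 perturbed patterns in
three 25-member families (L1 1.05–1.5 with deep layers 0.3–0.6, fixed
member 1.3/0.5; L1 1.05–1.5 with deep layers 0.6–2.0, fixed member
1.1/0.7; one uniform value 1.05–1.5 in all layers, fixed member 1.1),
each family drawn from its own seeded substream.

## Numerics

Integration is explicit forward Euler with a fixed step, default
dt = 0.01 h, from an all-zero initial state. Steady state is declared
when the largest per-cell, per-species derivative magnitude drops below
`steady_tol` (default 1e-8 a.u./h); a hard cap `t_max = 2000 h`
bounds runaway configurations. A stability guard refuses step sizes
with `dt × (fastest per-cell loss rate + D × max degree) ≥ 1`, using
the a-priori miR171 ceiling `k_mirp max[ML1p] / k_mirn`; it can be
overridden, in which case divergence (non-finite values or any
concentration above a ceiling, default 1e6 a.u.) raises. Under the
guard, all concentrations remain non-negative. Parameter sweeps batch
many runs into lock-step array operations; each batch row performs
exactly the arithmetic of a single run, so batched and single results
are bit-identical and screening is a pure map over its inputs.

Two independent oracles check the integrator: the single-cell closed
form (exact at `D_mir171 = 0`) and a sparse linear solve of the miR171
fixed-point system `(k_mirn I − D L) m = k_mirp [ML1p]` followed by
the elementwise closed forms (exact for any D). Both live in the
library but are never used by the screening path.

The written equation uses a single diffusion constant already rescaled
by cell size, and that is the default behaviour. Because "rescaled by
cell size" is ambiguous between a uniform constant and a per-cell
rescaling, an optional per-edge mode is provided behind the
`volume_scaled_diffusion` flag: each edge weight is divided by the
mean volume of the cell pair (normalised by the template's mean cell
volume so both modes share the scale of D). The weighted operator
remains symmetric, so material is still conserved; the flag is off by
default and none of the shipped results use it.

## Baseline parameters

The original study's baseline table is not available, so the package
ships its own documented baseline, selected from the stated search
ranges so that the wild-type simulation on the 1216-cell template
passes the gradient classifier: `k_mirp = 0.9`, `k_mirn = 0.1` (1/h),
`D_mir171 = 0.005` (area a.u./h), `k_hrp = 0.5` (a.u./h),
`k_hrnm = 0.9` (1/(a.u.·h)), `k_hrnh = 0.1` (1/h), and all six
protein/reporter rates at 0.5. With these values the wild-type corpus
mean *HAM* mRNA is ≈ 4.1 a.u., the epidermal/corpus ratio ≈ 0.016, and
the miR171 penetration depth ≈ 0.2 cell diameters beyond the source
layer — deep-layer miR171 comes almost entirely from the immediately
adjacent shell. These are *not* the original authors' values; every
result that depends on the baseline is reported against this set.

## Pattern classification

The experimental readouts being qualitative, the classifiers fix
explicit thresholds and record them with every verdict.

*Wild-type gradient*: pass iff the epidermal mean *HAM* mRNA is below
`l1_ratio_max` (default 0.2) times the corpus mean, the three layer
means increase strictly from L1 through L2 to corpus, the corpus mean
exceeds `corpus_floor` (default 0.1 a.u.), and the (immobile) GFP
reporter protein stays epidermal (corpus mean < 5 % of the L1 mean).
Tightening any threshold can only turn passes into failures.

*Suppression* (ectopic vs. matched wild type, identical parameters and
template): pass iff mean *HAM* mRNA is strictly reduced in every layer
and reduced at least (1 − threshold)-fold (default threshold 0.5) in
the sub-epidermal layers. The epidermis is held to strict reduction
only: its wild-type level is already near zero, and raising L1
`[ML1p]` from 1.0 to at most 1.5 can reduce epidermal *HAM* mRNA by at
most ~33 %, so a fold-change demand there would be unsatisfiable by
construction and would not reflect what "suppression in all layers"
means for this cascade.

## Parameter searches and sensitivity

The local search is a one-at-a-time grid: each of the six key
parameters (`k_mirp`, `k_mirn`, `k_hrp`, `k_hrnm`, `k_hrnh`,
`D_mir171`) is scaled through 40–200 % of baseline at 2 % intervals
with the others fixed — 6 × 80 variants plus the baseline, 481 unique
sets; only the one-at-a-time design is consistent with that count (a
full factorial would be 81⁶). The unbiased search draws from a
scrambled Sobol sequence, mapped log-uniformly onto the bounds
(five rates 0.1–1, diffusion 0.001–0.1), with an explicit seed.
Unconverged or unstable sets are recorded as flagged non-hits.

Normalized sensitivity of the output m (total steady-state *HAM* mRNA
summed over cells; sums and means give identical normalized values) to
parameter p is the one-sided elasticity `(Δm/Δp)(p/m)` at a +1 %
perturbation. The perturbed run integrates for exactly the duration
the base run needed, rather than to its own stopping time, so the
finite difference is free of stopping-time noise; this makes the
structural identities exact in floating point — S(k_hrp) = 1 (the
*HAM* mRNA equation is linear in `k_hrp` and miR171 is independent of
it) and S = 0 for all six downstream protein/reporter rates. Across
hit ensembles the magnitude ranking consistently places `k_hrp`,
`k_hrnh` and `k_mirn` above `k_mirp`, `k_hrnm` and `D_mir171`; note
`S(k_mirp) = S(k_hrnm)` identically (both enter only through the
product `k_hrnm · miR171`), and `S(k_hrnh) + S(k_hrnm) = −1` when m is
corpus-dominated, which is why the split is robust for gradient-forming
parameter sets.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 1216-cell
template for the 75-pattern robustness result (76 simulations) and
reduced-scale versions elsewhere: a 300-cell, four-shell dome (same
cell size, smaller footprint) for the 2,000-set random-search rerun,
the hit-ensemble sensitivity profile and the ectopic direction checks,
and ~60-cell/12-cell domes for unit-level properties. These sizes were
chosen as the smallest templates that retain all three layers and a
corpus-dominated output.

## Known limitations

* The reduced random search classifies ~11–12 % of log-uniform draws
  as gradient-forming under the default explicit criteria — an order
  of magnitude more permissive than the full-scale reference rate
  (173/20,000 ≈ 0.9 %) reported for a human qualitative screen. The
  explicit rule admits weak-gradient solutions (the strict-monotonicity
  check is satisfiable by arbitrarily small layer differences) that a
  visual screen would reject; the hit *fraction* should therefore be
  read as criterion-dependent, while the properties of the hit set
  (layer ordering, sensitivity split) are robust.
* Exact hit counts (235/481, 173/20,000) are not reproducible without
  the original baseline values and acceptance rule; the package treats
  them as order-of-magnitude reference points only.
* Forward Euler with dt = 0.01 h is the reference integrator by
  design; halving dt changes total steady-state *HAM* mRNA by < 0.1 %,
  but stiff user-supplied parameter sets are refused by the stability
  guard instead of being integrated implicitly.
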