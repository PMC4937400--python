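# Methods and conventions

This note records the scientific conventions, defaults and numerical
choices the package commits to, and what its synthetic validation does
and does not demonstrate about real MD data.

## Units

Coordinates and distances in Å, time in ps, angles in degrees,
temperature in K. Diffusion coefficients are reported in m²/s
(1 Å²/ps = 10⁻⁸ m²/s). Atom indices are 0-based internally; 1-based
only at file-format boundaries (PDB serials, resids).

## Hydrogen-bond criterion

A candidate is every (donor hydrogen, acceptor oxygen) pair in which the
acceptor is not the hydrogen's own covalent parent. The pair is a bond
iff

* minimum-image distance between the *donor oxygen* and the acceptor
  oxygen ≤ `d_max` (default 3.5 Å — the first minimum of the O–O radial
  distribution function in these glasses), inclusive; and
* the O-H···O angle, measured *at the hydrogen* between the H→donor-O
  and H→acceptor-O minimum-image arms, > `theta_min` (default 150°),
  strict. 180° is perfectly linear.

The vertex-at-hydrogen convention is fixed, not configurable: the 150°
threshold only makes sense in this reading (vertex at either oxygen
would make near-linear bonds score near 0°). The distance criterion is
O–O, not H···O. Boundary semantics (≤ for distance, > for angle) follow
the definition's wording. All census operations default to
intermolecular bonds only; intramolecular detection is available behind
a flag for diagnostics.

Covalent H→O parentage always comes from the topology sidecar or the
name convention, never from geometry: in a dense glass, non-bonded
O···H contacts approach covalent distances and distance-based
perception misassigns.

Two detectors are maintained: a brute-force O(n_H·n_O) reference and a
cell-list detector (cell edge ≥ d_max, 27-cell walk). They are required
to produce identical, identically ordered output; the cell-list path
falls back to brute force when a box edge admits fewer than three cells,
where a modular cell walk would double-count periodic neighbours.
Boxes are orthorhombic only; triclinic input is rejected rather than
silently wrapped, which keeps the minimum-image arithmetic exact and
the oracle trivial. Analysis requires every box edge ≥ 2·d_max.

## Network statistics

* **Stoichiometry** per class c: N_c / (number of molecules
  participating in ≥1 bond of class c), per frame; undefined (reported
  absent, never 0) when no molecule participates. A molecule acting as
  both donor and acceptor counts once per class.
* **Clusters**: connected components of the graph whose vertices are
  all sugar molecules and whose edges are t-t bonds with multiplicity
  collapsed — clustering is about connectivity, while the census counts
  every bond. Isolated molecules are 1-body clusters, so cluster sizes
  always sum to the sugar count. The full histogram is reported; the
  three-bin view (n > 200, 1 < n < 6, n = 1) is a convenience.
* **Bound water**: ≥1 t-w or w-t bond; w-w bonds confer nothing. "No
  contact" is operationalized as "no H-bond to sugar" — the testable
  reading of the two phrasings in circulation.
* Frames are statistically independent samples: statistics are computed
  per frame and averaged as mean ± sample standard deviation (ddof 1;
  sd 0 for a single frame). Bonds are never pooled across frames.

## Diffusion

MSD uses every time origin (FFT/autocorrelation algorithm, O(T log T)
per coordinate) on an unwrapped trajectory; unwrapping requires uniform
frame spacing and per-step displacements under half a box edge, and
errors otherwise rather than guessing images. The diffusion coefficient
is the least-squares slope of MSD(τ) over lags in [10%, 50%] of the
maximum lag, divided by 6. The window default excludes the
ballistic/rattling short-time regime and the poorly averaged long-lag
tail; both bounds are configurable. When the log-log slope of the MSD
in the window deviates from 1 by more than 0.2 the estimate is emitted
with a sub/super-diffusive warning rather than suppressed. Name
selections (`O16`, `HO16`, …) pool every atom carrying that name —
i.e. both symmetric glucose-ring copies when a full sugar topology is
loaded.

## Radial distribution function

g(r_k) = pair count in shell k / (n_ref · ρ_target · 4π r_k² Δr),
averaged over frames, with the bin-centre radius rather than the exact
shell-volume difference (the difference is < 0.5% beyond 2 Å at the
default Δr = 0.05 Å). Pair counting uses a periodic KD-tree; self-pairs
(identical atom index) drop out of every bin. The first-minimum
extractor smooths with a 3-bin moving average (optional), finds the
first local maximum, then returns the bin centre of the first strict
local minimum after it — the *first* trough, not the global minimum —
and raises on monotone input.

## Curve models and fits

The Gaussian viability parameterization is fixed as
y = y0 + A·exp(−(x−xc)²/(2w²)) — plotting packages differ on whether A
is an amplitude or an area, and the amplitude form is the common one;
the fitted peak is y0 + A at xc. EC50 is the 0.5 crossing of the
*fitted* curve on the descending low-water branch (x < xc), found by a
512-point bracket scan plus Brent root-finding to 1e-10; when y0 = 0 and
A = 1 it equals the closed form xc − w·√(2 ln 2), which the tests check.
A curve that never reaches 0.5 on that branch has no EC50 and raises.

The two Gordon–Taylor-form fits always use mass fraction x_t as the
internal abscissa (inputs given as water content are converted through
x_t = 1/(1+R)), which removes the distortion of log-scaled
water-content display axes. The pure-component values (Tg_t, Tg_w;
N_pure) are fixed inputs, never fitted. N_inf ≥ 1 is expected on
physical grounds (a molecule that bonds at all shares at least one
bond); a fit below 1 is flagged and warned about, not rejected.

Nonlinear fits run deterministic multi-starts on a small parameter grid
(8 starts for the two-parameter stoichiometry fit, 9 for the Gaussian)
with Levenberg–Marquardt, positivity of k and w enforced through log
parameterization; there is no random initialization anywhere, so fits
are bit-reproducible without a seed. Degenerate data (constant y, flat
viability) short-circuits to a flagged result instead of a spurious
minimum. Fits are unweighted by default with optional per-point
weights; R² = 1 − SS_res/SS_tot is reported alongside.

## Composition

Molar masses default to anhydrous trehalose (342.30 g/mol) and water
(18.015 g/mol); dry weight is sugar mass only. `waters_for_content`
returns the *smallest* count reaching the target — the convention under
which 216 sugars need exactly 8209 waters for 2 gH₂O/gdw — and is the
exact inverse bound of `content_from_counts`.

## Synthetic data: what it emulates, what it does not

The planted-network generator realizes a requested bond adjacency as
coordinates plus topology with a construction-level guarantee that the
default detector returns exactly the planted bonds. Molecules are
minimal stand-ins — one hub oxygen plus one hydroxyl hydrogen per
donated bond (waters always carry exactly two hydrogens) — because
every analysis consumes only roles and positions; full 45-atom sugar
geometry would add nothing to the statistics being validated. Bonded
molecules occupy adjacent sites of a cubic lattice with edge equal to
the bond O–O distance (default 2.8 Å, safely inside the criterion) and
hydrogens lie exactly on the bond axis (180°). The direction set is
octahedral, which makes the construction provably clean: non-bonded
lattice neighbours are either ≥ √2·2.8 = 3.96 Å apart (outside the
distance cutoff) or fail the angle test by ≥ 100°; spare water
hydrogens are pointed only at unoccupied sites. Connected groups are
packed on a coarse grid with ≥ 6 Å between bounding boxes, placement
uses backtracking self-avoiding embedding, and the result is verified
against the brute-force detector anyway, with re-seeded retries. The
union bond graph must therefore be a **forest** with ≤ 6 distinct
neighbours per molecule and ≤ 2 donations per water; cyclic adjacencies
are reported as geometrically infeasible rather than approximated.
Chains, spanning trees and water stars — the configurations the
analyses are validated on — are all forests.

The random-walk generator draws i.i.d. Gaussian steps of per-axis
variance 2·D·Δt, so MSD(τ) = 6Dτ holds exactly in expectation and the
empirical deviation shrinks as 1/√(n_atoms·n_origins). The ideal-gas
generator gives uniform positions (g(r) ≡ 1). All generators are
bit-reproducible from an integer seed.

What passing these tests shows: the detector, the graph statistics, the
MSD/diffusion estimator and the RDF normalization are each correct
against independent ground truth. What it does not show: anything about
force-field realism — synthetic frames have no excluded volume,
realistic densities, correlated motion or sub-diffusive caging, so the
published MD-scale numbers (≈3.8 bonds per molecule in the dry glass,
≥90% bound water below 0.1 gH₂O/gdw, >200-molecule clusters,
D ≈ 10⁻¹³ m²/s) can only be reproduced from actual simulation output,
not from these generators.

## Problem sizes used in validation

Detector equivalence runs on 100 random frames of 30–250 waters in
12–34 Å boxes; planted-network round trips on 100 random forest specs
of 6–36 molecules; diffusion recovery on 1000 walkers × 2000 frames at
D = 7.5×10⁻¹⁴ m²/s across 5 seeds (tolerance 5%, consistent with
sampling theory at that size); the ideal-gas flatness check uses 4
frames of 5000 atoms in a 40 Å box with Δr = 0.1 Å, where the worst-bin
Monte-Carlo error is ≈3.5%, against a ±5% band.

## Known limitations

* Orthorhombic boxes only; no triclinic support by design.
* O–H donors only (no N–H), one criterion family (geometric; no
  energetic/orbital definitions), no H-bond lifetime or rotational
  dynamics.
* The cluster machinery covers sugar–sugar networks; water–water
  clustering and percolation thresholds are out of scope.
* PDB coordinates carry the format's 3-decimal precision; use the
  extended-XYZ path when round-trip exactness matters.
* The viability Gaussian is a descriptive fit for interpolating a dose
  response, not a mechanistic model; no Hill/4PL alternatives are
  offered.
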