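# Methods

## The model

The package analyses potential-energy landscapes through their stationary
points. A landscape is catalogued as local minima `a` with energies `E_a`,
log products of positive normal-mode frequencies `L_a = sum_i ln nu_{a,i}`,
degeneracy weights `n_a`, and the index-1 saddles (transition states) that
connect them. Thermodynamics is computed in the classical harmonic
superposition approximation (HSA): the total partition function is the sum
of harmonic partition functions of all catalogued minima. Writing the
temperature axis as `T = kBT` in energy units, each minimum carries the
log-weight

    ln w_a(T) = ln n_a - E_a / T + kappa ln T - L_a

(additive constants common to all minima dropped), where `kappa` is the
number of vibrational degrees of freedom, shared across the database.
Occupation probabilities are `p_a = w_a / sum_b w_b`, the mean energy is
`<E> = kappa T + sum_a p_a E_a`, and the heat capacity in units of kB is

    CV / kB = kappa + (<E^2> - <E>^2) / T^2

with the variance over the minima energies under `p_a`. The classical form
is used because it makes this variance identity exact; a quantum-harmonic
variant is out of scope. All occupation arithmetic is done in the log
domain (log-sum-exp), so the curves are overflow-safe at any temperature.
The derivative `dp_a/dT = p_a (E_a - <E>_c) / T^2` uses a twice-compensated
mean so that `sum_a dp_a/dT` vanishes to ~1e-16 even after the `1/T^2`
amplification at low temperature.

Low-temperature CV features — peaks and inflection points — diagnose
competition between structurally distinct low-energy minima. Peaks are
interior local maxima of CV; inflections are interior local maxima of
`dCV/dT` not adjacent to a peak. HSA curves are analytic, so no smoothing
is applied; a relative prominence floor of `1e-3 * max(CV)` suppresses
numerical ripple. The analysis protocol keeps the first feature above a
threshold temperature (default `threshold_low = 0.086` in the energy units
of the data; the alternative low cut 0.076 and the upper cut 0.300 bound
the window used for propensity correlations). The melting peak is
identified as the highest-kBT peak on the grid — which requires the grid to
extend past it — and is excluded by default. Each feature is decomposed
into the minima whose occupations grow (`dp_a/dT > 0`) or drain
(`dp_a/dT < 0`) at the feature temperature; within each sign group, minima
are sorted by `|dp_a/dT|` (ties to the lower id) and the shortest prefix
covering 98% of the group total is reported. Coverage is applied per sign
group, matching the two-colour visualisation in disconnectivity graphs.

## Sampling

Basin-hopping proposes a perturbation, quenches to the nearest minimum
(limited-memory quasi-Newton, convergence = RMS gradient below tolerance,
iteration cap 10,000), and accepts on quenched energies with a Metropolis
rule at temperature `kBT`. Every converged quench enters a capacity-bounded
pool of the lowest-energy distinct minima; the production protocol keeps
the 1000 lowest and finally re-converges them to an RMS gradient of 1e-7.
Two structures are duplicates iff their energies differ by less than 1e-6
*and* their best-aligned (centroid + Kabsch) RMSD is below 1e-3; no
permutation matching is attempted, so permutational isomers are stored as
distinct entries, which is harmless for the quantities computed here.

The move set combines Cartesian displacements (uniform per coordinate,
fixed step size by default — an adaptive scaling towards 50% acceptance
exists but is off for reproducibility), torsional group rotations for
chains (a random tail segment rotated about its preceding bond axis), and
rigid-body dimer moves: centroids expanded radially from the overall
centroid, an angle-axis rotation about each monomer centroid, and a random
translation, interleaved with Cartesian moves at a default cadence of one
per 111. Parallel tempering runs replicas at temperatures in geometric
progression (default 16 between 300 and 575, matching the production
protocol; toy runs pass reduced values) with Metropolis swaps between
adjacent temperatures every 10 steps (the interval is a package choice).
Sampling temperatures and the analysis kBT grid are independent settings.
A single production-scale run would use ~6e5-8e5 basin-hopping steps;
desk-scale runs here use at most 2e4.

For Lennard-Jones clusters the quench (energy, gradient, analytic Hessian,
L-BFGS with Armijo backtracking plus an eigenvalue-filtered Newton polish)
is JIT-compiled with numba; at the step counts used for the LJ benchmarks
(~1e5 quenches) a Python-level minimiser would dominate the runtime. The
compiled path is validated against the generic scipy path in the tests and
falls back to it for starts it cannot converge.

## Transition-state searches

Candidate saddles between two minima come from a doubly nudged elastic
band: 11 images (default), spring constant 1.0, upwind tangents, with the
perpendicular spring component double-nudged off the true-gradient
direction. The band is relaxed with FIRE (velocity quenching, displacement
capped at 0.05 per iteration); plain fixed-step descent oscillates on
surfaces with gradient scales of 1e2-1e3. Interior images that are local
maxima along the relaxed band are refined by hybrid eigenvector-following:
an uphill step along the softest non-zero Hessian eigenvector combined with
Newton minimisation in the orthogonal complement, trust radius 0.2,
classified as an error if the walk lands on a minimum or a higher-index
saddle. Hessians are central finite differences of the analytic gradient
(step 1e-5); eigenvalues with `|lambda| < 1e-6` are zero modes (6 for 3D
clusters and chains, none for single-particle 2D surfaces) and are excluded
from `L_a` and `kappa`. Each refined saddle is connected to its two minima
by quenches started 1e-3 either side along the reaction mode,
giving a minimum-TS-minimum triple; the barrier invariant
`E_ts >= E_min - 1e-8` is enforced on insertion.

Which unconnected pair to attempt next is chosen by Dijkstra's algorithm on
the complete graph where TS-connected pairs have weight zero and
unconnected pairs the squared best-aligned RMSD of their minima (the
distance metric is a config choice); the first gap edge on the
minimum-weight source-sink path is attempted, and pairs that failed before
get infinite weight. Databases are used as grown; no barrier-removal
post-processing is applied.

## Disconnectivity graphs

At threshold `V` two minima share a superbasin iff a path of transition
states with energies `<= V` joins them (union-find; labels are the smallest
member id). Trees are built by sweeping thresholds downwards in uniform
steps `delta_e` (default `(e_top - E_gm)/50`) from `e_top` (default just
above the highest saddle): an internal node's final energy is the lowest
threshold at which its members still interconvert, so junction heights
over-estimate the true connecting saddle by at most `delta_e`; leaves sit
at their minima's own energies. Layout x-coordinates come from recursive
subtree-size ordering. Leaves can be coloured from feature contribution
sets with first-feature precedence on overlap.

## Structural descriptors

Two order parameters separate hexapeptide-like conformations: the
end-to-end distance between two selected sites, and the signed IUPAC
torsion over four ordered sites, reported in degrees in (-180, 180].
Site selection is explicit; for bead-chain toys a convenience mapping uses
the chain ends and torsion sites at fractional positions 0, 2/5, 3/5 and 1
(the bead analogue of taking the backbone of residues 1, 3, 4, 6 of a
hexapeptide). Hairpins sit at small distance and small dihedral, helices at
larger values of both, extended chains at the largest distances with
torsions near ±180. Conformation classes (hairpin, S-shaped, question-mark,
W-shaped, extended) are assigned by half-open distance bins whose cut
points are configuration values — the class ordering is physical, the cuts
are not, so the defaults are toy-scale conventions. For dimers, descriptors
are computed and reported per monomer (two records per structure), and the
minimum inter-monomer site distance ("interstrand separation") is an
auxiliary descriptor separating tightly packed from loosely associated
dimers. Correlation-plot extraction takes the union of a feature's
positive and negative contribution sets, optionally restricted to minima
within an energy window of the global minimum (default 2.6 energy units,
the dimer protocol value); for monomer-style analyses the window can be
disabled and contributors-only is the default. The quantitative proxy for
the visual "spread" of a correlation plot is the range and standard
deviation of both descriptors. Rank correlation of first-feature
temperatures against externally supplied aggregation-propensity scores uses
Spearman's rho, with rows lacking a feature excluded and listed, plus an
optional per-group check of whether the amyloid member has the lowest
feature temperature in its group.

## Toy potentials

Three differentiable stand-ins (reduced units) exercise the machinery; the
peptide force field itself is out of scope.

* Mueller-Brown: the standard four-Gaussian 2D surface (3 minima, 2
  saddles) used to verify the transition-state pipeline against a
  grid-scan + Newton oracle.
* Lennard-Jones clusters (epsilon = sigma = 1): the basin-hopping
  benchmark; reference lowest energies for LJ7 (-16.505384) and LJ13
  (-44.326801) are reproduced by long in-repo reference runs.
* Bead chain: harmonic bonds (k = 100, r0 = 1), harmonic angle bends
  (k = 10, theta0 = 108°) — the bend term is needed to keep 1-3 distances
  bounded and dihedrals non-degenerate — a cosine-series torsion
  `0.8 (1 + cos phi) + 1.2 (1 + cos 3 phi)` with trans and gauche wells,
  and attractive LJ (epsilon = 0.6, sigma = 1.1) between beads three or
  more bonds apart, so compact (gauche, nonbonded-stabilised) and extended
  (all-trans) backbone basins compete as in short peptides. Configurations
  with pair distances below 1e-6 sigma are rejected.

## Synthetic data

Real hexapeptide landscapes are multi-funnel: groups of minima whose
bottoms differ in energy and vibrational entropy, separated by barriers
much larger than the intra-funnel ones. The funnel generator draws
intra-funnel energy ladders from an exponential distribution above each
bottom (scale = the funnel's spread; dense low-lying spectra), controls
entropy through a constant `L_a` offset per funnel (negative offset =
vibrationally entropic funnel, favoured at high temperature), connects each
funnel internally through its bottom with barriers at 25% of the
inter-funnel barrier, and joins funnel bottoms at the inter-funnel barrier.
A high-energy, strongly entropic "melting band" (default: 5 minima at +3.0
with `L` offset -5) reproduces the high-temperature melting peak that the
first-feature rule assumes exists, so the designed low-temperature peak is
never itself the highest-kBT peak. When a target feature temperature is
requested, the generator solves numerically (bracketed root find on the
dense-scan peak position, with the funnel-weight crossover as fallback
objective) for the common shift of the upper funnel bottoms that places the
funnel-competition peak at the target; the manifest records the solved gap.
Transition-state `L` values are the mean of the connected minima minus 0.5;
thermodynamics never uses them, they only exercise I/O.

Conformer generators build hairpin (two antiparallel arms with a slight
out-of-plane pucker), helical (right-handed, ~3.6 sites/turn, positive
twist) and extended (planar all-trans zigzag, torsion exactly 180°)
templates with Gaussian site jitter (default sd 0.05), and record each
sample's exact descriptors in a truth table alongside the template's design
values. Dimer configurations place two independently jittered, randomly
oriented monomers at a given centroid separation. Funnel databases attach
jittered conformer coordinates per funnel (funnel f uses family f mod 3) so
the descriptor stage runs end-to-end on generated data. All generators are
bit-reproducible from their seeds.

What the generators deliberately do not emulate: force-field energetics,
realistic vibrational spectra, correlated energy-entropy statistics of real
peptide minima, or all-atom geometry. Passing tests therefore demonstrate
the correctness of the analysis machinery on landscapes with the assumed
statistical structure, not the transferability of any biological conclusion.

## Problem sizes and numerical conventions

Test and verification runs use desk-scale sizes chosen as the package's
own defaults: LJ7 at 5e3 and LJ13 at 2e4 basin-hopping steps over 5 seeds,
synthetic databases of ~25-200 minima, kBT grids of 400 log-spaced points
(dense scans use 2e5), and 20-seed recovery experiments. Internal ids are
0-based; flat files use 1-based ids. Energies are free-form floats with
units declared in metadata (default "reduced"). Tolerances: deduplication
1e-6 (energy) / 1e-3 (RMSD), zero modes 1e-6, barrier slack 1e-8, tight
RMS gradient 1e-7. CV is reported as total CV/kB including the kinetic
`kappa` offset — a constant that shifts no feature location; `kappa` is
stated in every database's metadata.

## Known limitations

* The harmonic superposition approximation ignores anharmonicity and
  inter-well interference; it is the standard desk-scale estimate, not a
  converged thermodynamic calculation.
* Hybrid eigenvector-following builds dense finite-difference Hessians:
  fine at toy dimensionalities, not intended for hundreds of atoms.
* Minima-pool deduplication does not match particle permutations, so pool
  occupancy (not correctness) is wasted on permutational isomers of
  clusters.
* Melting-peak identification requires the temperature grid to extend past
  the melting maximum; on truncated grids the highest detected peak is
  mislabelled.
* The Dijkstra pair-selection weight (squared best-aligned RMSD) is one of
  several reasonable structural distances; it is a configuration choice,
  not an optimum.
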