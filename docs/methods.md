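# Methods

This note records the models, conventions and numerical choices behind
`redoxtraj`, and what the synthetic fixtures do and do not establish about
real molecular-dynamics data.

## Coordinates, superposition and fluctuation metrics

All coordinates are Cartesian Ångström, all times picoseconds; there is no
unit autodetection. Rigid-body motion is removed by a Kabsch least-squares
fit: the optimal rotation comes from the SVD of the 3×3 correlation matrix
with the determinant-corrected singular value, so reflections are never
selected — molecular chirality is preserved even when a mirrored match
would score better. Fits refuse fewer than three atoms or collinear
selections, where the rotation is not unique. A batched implementation
(`batch_rmsd`) evaluates thousands of frame-to-reference RMSDs through
vectorized 3×3 SVDs; it is algebraically identical to the per-frame path
and is what the clustering stages use.

RMSD series accept distinct fit and measure masks. With identical masks
this is the standard fitted RMSD; with different masks each frame is
superposed using the fit mask only and the deviation is measured over the
other mask without refitting, which isolates the rigid-body displacement
of one domain (e.g. a luminal loop) relative to another (a transmembrane
bundle).

RMSF defaults to fluctuation about the time-mean conformation after
superposition (the variance-minimizing reference, computed in one
fit → mean → refit pass, not iterated to a fixed point); fluctuation about
the initial frame is available. Note a finite-size effect that matters
when validating against closed forms: superposition removes six degrees of
freedom from 3N coordinates, so an isotropic ensemble with per-coordinate
spread σ yields RMSF slightly below σ√3, by a factor of roughly
√(1 − 6/3N). Tests therefore either use displacement fields orthogonal to
the rigid-body modes or enough atoms that the depletion is below the
tolerance.

The high-fluctuation exclusion rule keeps atoms with RMSF strictly below a
threshold (default 4 Å) in a single pass: profile once, exclude, done.
Iterating to a fixed point was considered and rejected as under-specified;
one pass is reproducible and transparent.

## Covariance, PCA and cross-correlation

The covariance is the population (1/F) estimator over fitted frames —
the time-average form — and deviations are always taken about the time
mean even when the superposition target is the initial frame. Eigenvalues
are reported in descending order; the trace identity Σλ = tr C holds to
machine precision and is asserted at 1e−8. Projections are computed as
Vᵀ(x − ⟨x⟩), so the mean conformation scores zero.

Cross-correlation works on per-atom 3-vector displacements. Zero-variance
atoms make the coefficient undefined; they are reported as 0 with a
warning. Superposition couples atoms weakly (order 2/N), which is
invisible for protein-sized selections (~150 Cα, the length of a typical
thioredoxin-fold domain) but dominates toy systems; the independence
checks therefore run either unfitted or at protein scale. PC scores are
unweighted (no mass weighting): the analyses operate on Cα selections
where masses are equal, and no statement in scope depends on weighting.

## Ensemble clustering

The algorithm is deliberately the simple two-step randomized procedure and
nothing else (no k-means/hierarchical alternatives). Harvesting removes
the closed ball of radius r around each random pick, which guarantees the
surviving references are pairwise strictly more than r apart — asserted as
an invariant. Assignment is nearest-reference by fitted RMSD even when
that distance exceeds r (the second step does not re-threshold), with ties
broken to the lowest reference index; all frames are assigned, including
those removed during harvesting. Seeds are mandatory in the CLI because
the reference set is a random function of the draw order. The default
cut-off grid is 1.6–3.0 Å in 0.2 Å steps and "dense" clusters are those
above 4% population, applied after merging for merged-replica runs.
Representatives are medoids (minimum mean fitted RMSD to cluster members,
lowest frame id on ties).

## Motif, tetrahedron and helix geometry

The CX₁X₂C motif is summarized by the S⋯S′ distance and the absolute
pseudo-torsion S−Cα−Cα′−S′ (absolute value makes the landmark ordering
immaterial up to sign). Klyne–Prelog bands on the absolute torsion are
[0°, 30°) syn-periplanar, [30°, 90°) synclinal, [90°, 150°) anticlinal,
[150°, 180°] antiperiplanar — the standard nomenclature, since only the
class names are fixed by usage. S-H⋯S hydrogen-bond probabilities use the
same geometric criteria as the general detector (D⋯A < 3.6 Å, angle at
H ≥ 120°, configurable) and require explicit thiol hydrogens: thiol H
positions carry the directionality of the statistic and are never
idealized.

Tetrahedron series report the six edge distances between four Cα anchors
per frame; anchors are user configuration (a helper proposes per-segment
RMSF extrema). A synchronous-change detector flags frames where at least
three edges jump by a configurable Δ between consecutive samples.

A helix axis joins the centroids of the main-chain atoms {N, Cα, C, O} of
the first and last residues of the range; an elongation factor stretches
the segment symmetrically for display. Drift analysis superposes frames
on a common reference (configurable mask — in practice the static domain)
before projecting the endpoints on the x–z and y–z planes.

## Kendall shape space

Preshapes are centered, unit-Frobenius-norm landmark arrays. The geodesic
distance optimizes over proper rotations only; reflection identification
is deliberately not used because S−Cα−Cα′−S′ handedness is physically
meaningful. The distance is evaluated through the chord,
d = 2 arcsin(‖a − b*‖/2), which is exact and numerically stable near
coincident shapes (the arccos form loses half the significant digits).
Convention: d is the unit-preshape-sphere angle, in [0, π/2] for
non-mirrored matches; on this convention the equilateral-to-collinear
triangle distance is π/4. The classical triangle shape sphere of radius ½
is recovered by doubling the angle: the disk map uses colatitude
θ = 2·d(T, equilateral) and plots (r, φ) = (sin θ, longitude), putting the
equilateral triangle at the centre (r = 0) and collinear triangles on the
rim (r = 1). The longitude zero-meridian is fixed by a labeling
convention: the tangent direction at the pole toward the isosceles
triangle elongated along vertex 1; the second basis vector's orientation
follows the construction order deterministically. The boundary of the
H-bond-favourable region on the disk is not hard-coded: it is whatever
predicate the user supplies, since no closed-form criterion is defined.

MDS uses classical (Torgerson) scaling as initialisation and SMACOF
majorization (scikit-learn's implementation) for refinement; the reported
stress is Σ over ordered pairs of squared discrepancies, computed
directly. Majorization never increases stress, and Euclidean-realizable
inputs embed exactly at the Torgerson step already. The Fréchet mean uses
tangent-space log/exp (Karcher) iteration with gradient tolerance 1e−8
and at most 1000 iterations, initialized at the normalized aligned
arithmetic mean; non-convergence raises with the last gradient norm. For
two shapes this converges to the geodesic midpoint; in the flat
(small-dispersion) limit it coincides with the arithmetic mean.

## Contacts

Hydrogen bonds consider N, O and S heavy atoms as donors (if they carry a
hydrogen) and acceptors, with D⋯A < 3.6 Å and ∠D-H⋯A ≥ 120° at the best
available hydrogen; sulphur pairs use the same defaults. Backbone amide
hydrogens may be idealized (1.0 Å from N, anti-parallel to the preceding
C=O) when absent; side-chain and thiol hydrogens must be explicit.
Attached hydrogens are found through the bond list when present, else by
proximity within 1.45 Å in the same residue (S-H bonds reach ~1.35 Å).

Salt bridges use the operational rule side-chain N of Arg {NE, NH1, NH2}
or Lys {NZ} within 4.0 Å of side-chain O of Asp {OD1, OD2} or Glu
{OE1, OE2} — the community convention, exposed as a knob, chosen because
the conceptual definition (paired ionic + hydrogen bonding) carries no
number. Histidine is excluded as a donor by default (neutral,
ε-protonated convention). A residue pair can legitimately appear as both
hbond and salt bridge; consumers count unique residue pairs via
`count_unique_contacts`.

Hydrophobic contacts require two hydrophobic residues (A, V, L, I, P, F,
M, G) with side-chain heavy atoms within 4.0 Å; glycine's Cα is its
side-chain proxy, without which glycine-mediated packing contacts are
invisible. Within a chain, residues closer than two positions in sequence
are skipped (their side chains are covalent neighbours); cross-chain pairs
never are. The exposed-residue report is a contact-based proxy — residues
whose side chains join no intra-molecular contact at the configured
cut-offs — and is explicitly not a solvent-accessible-surface computation.

## Secondary structure

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
model, E = 0.42·0.20·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
bonded below −0.5 kcal/mol, with pairs closer than two residues in
sequence excluded. Helices need two consecutive turns: H spans i+1..i+4
when i→i+4 bonds start at i and i+1, G analogously with i→i+3. Strands
come from parallel/antiparallel bridge patterns, isolated turns give T,
Cα direction changes over ±2 residues above 70° give S, the rest is C.
Priority on conflicts is H > G > E > T > S > C. The π-helix label is
omitted (its patterns fold into T). This is not a byte-exact clone of any
particular DSSP release; agreement is asserted on ideal fixtures, where
the ambiguity of real-structure edge cases does not arise.

## Synthetic data: what it emulates and what it does not

Generators are deterministic under a seed and always emit their ground
truth (labels, spectra, planted contact lists).

* Gaussian ensembles sample x = ref + Σ_k √λ_k z_k q_k. When directions
  are not supplied they are drawn from the orthogonal complement of the
  six rigid-body modes of the reference, so the planted spectrum survives
  the superposition step of the analysis essentially unchanged.
* Multi-state trajectories draw states i.i.d. from occupancies or from a
  Markov chain when a transition matrix is given, then add isotropic
  Gaussian jitter per atom per coordinate (the simplest model consistent
  with RMSF assumptions). `displaced_states` rescales rigid-complement
  displacement fields by a 1-D root find until the *fitted* inter-state
  RMSD matches the requested value, so "8 Å apart" means what the
  clustering stage will actually measure.
* Ideal backbones are built from internal coordinates (φ/ψ of −57/−47 for
  α, −49/−26 for 3₁₀, 180/180 for extended; standard bond lengths and
  angles), which reproduces the canonical helix parameters (α: 1.5 Å
  rise, 100° twist; 3₁₀: ~2 Å rise, 120° twist) and i→i+4 O⋯H distances
  of 2.0–2.2 Å.
* Motif landmarks solve a symmetric-arm construction (Cα–Cα′ 5.0 Å,
  S–Cα arms 2.8 Å) with a bracketing root find so the built landmarks
  measure back the requested (distance, torsion) exactly.
* Planted interfaces string contact sites 30 Å apart along a line, each
  site holding a minimal donor/acceptor residue pair at the prescribed
  geometry; the spec validates a ≥0.1 Å / ≥5° margin against the
  detection criteria so round-off cannot flip a planted contact.
* The fused-VKOR cysteine stand-in (`make_synthetic_bvkor_cys`) places
  only cysteine SG landmarks: two intra-domain disulphide pairs at 2.05 Å
  plus a thioredoxin-like CXXC pair whose nearest sulphur sits a
  configurable distance (default 16 Å) from the VKOR-like active site.
  It is constructed geometry, not deposited coordinates, and exists so
  the inter-domain S⋯S measurement has a self-contained worked example
  exercising the full write → read → measure path.

Passing on these fixtures establishes the correctness of the geometry,
statistics and bookkeeping — not force-field realism. The generators have
no solvent, membrane, covalent constraints or anharmonicity; occupancy
recovery bounds are binomial, not kinetic; and results on real
trajectories will additionally reflect equilibration, sampling overlap
and topology quality, which are outside what the fixtures can probe.

## Problem sizes and tolerances

Default verification sizes: Gaussian-ensemble recovery uses 20–25 atoms ×
5000 frames (10% eigenvalue tolerance, |cos| > 0.95 eigenvector
recovery); decorrelation checks use 150 atoms; clustering recovery uses
20 atoms × 2000 frames with a 20-seed sweep (populations within ±3
points, the binomial 99% envelope at F = 2000); brute-force oracles run
on ≤10 landmarks / ≤200 atoms / ≤100 frames at 1e−6 agreement. MDS
declares exactness below 1e−6 stress; Fréchet iteration stops at gradient
1e−8. Structure round-trips assert 1e−3 Å, the PDB coordinate precision.

## I/O and configuration

PDB reading and writing are delegated to biotite behind the package's own
reader/writer surface (ATOM/HETATM accepted, first altloc kept, occupancy
ignored; one frame per MODEL; missing timestamps default to the frame
index in ps); a light pre-validation pass names the offending line for
the common malformations. The XYZ-per-frame dialect (count / comment /
element-x-y-z) is read and written directly. The pipeline is driven by a
YAML configuration (inputs, named selections, per-analysis parameters,
optional equilibration trim and a stepped-restraint schedule carried as
metadata with half-open [start, end) windows); every run writes CSV
tables, JSON summaries and a manifest with a configuration hash, seeds
and stage timings, so identical configs and seeds reproduce deterministic
outputs bit-identically. Equilibration trimming defaults to zero — any
discard window is an explicit analysis choice.
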