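# Methods

## Problem and model

`calvaria` simulates the quasi-static elastic response of an infant
calvarium to the two dominant oral behaviors of infancy — unilateral
(right-sided) chewing and suckling — and summarizes the resulting strain
regime at the cranial vault sutures.  The mechanical model is linear
isotropic elastostatics discretized with 4-node constant-strain tetrahedra;
bone and sutures are homogeneous isotropic solids (bone E = 6000 MPa,
ν = 0.27; sutures, fontanelles and the basicranial synchondrosis
E = 50 MPa, ν = 0.30).  There is no contact, no geometric or material
nonlinearity, no dynamics, and no intracranial pressure or brain growth:
the computed strains are the instantaneous elastic response to one loading
snapshot.

Coordinates follow craniometric convention: +x superior, +y anterior,
+z toward the patient's left, origin at the inter-condylar (TMJ) midpoint;
units are mm / N / MPa throughout.  Strain tensors are stored in the
*tensor* shear convention (ε_xy = ½γ_xy); reporting utilities accept an
`engineering_shear` flag that doubles shear components for comparison with
FE packages that print engineering shear.

## Synthetic geometry

Patient CT meshes are replaced by a parametric idealization:

* **Vault** — a thickened ellipsoid shell (default outer semiaxes
  55 × 70 × 52 mm, thickness 4 mm) meshed from a single structured grid via
  a concentric square→disk map and a radial offset.  The lateral and
  posterior rim reach colatitudes 124–130°, so the shell curves inward into
  a partial basicranial bowl; this stands in for the ring stiffness of the
  skull base (petrous/occipital anchoring) and is what lets the temporalis
  pull travel into the TMJ rather than leaving the temporal squama
  free-hanging.
* **Sutures** — full-thickness element strips along great-arc paths:
  metopic (nasion→bregma), sagittal (bregma→lambda, lambda at colatitude
  78°), paired coronal, lambdoid and squamous arcs, a nasofrontal band at
  the anterior rim, anterior/posterior fontanelle patches, and a
  basicranial synchondrosis band around the foramen magnum.  The coronal
  strip continues below the pterion toward the base and the lambdoid runs
  to the asterion rim, reflecting the unossified sphenoid/petrous suture
  complexes of infancy.  The mesh is conforming everywhere (shared
  interface nodes), which realizes bonded suture interfaces exactly.
* **Face** — the central anterior rim strip swept downward, through a
  quarter-circle bend, into a flat hard-palate plate (J-profile sweep of
  constant shell thickness).  The palate underside carries the pressure
  facets; its margin is the alveolar ridge with bite/latch landmark node
  sets.  There are no orbits, sinuses, tooth crypts or zygomatic arches.
* **Metopic closure** — label-only relabeling of metopic elements to bone
  along the arc-length parameter; the window seeds 10 % above the nasion
  and grows toward both ends in proportion, so windows nest and the nasion
  tip and fontanelle end close last ("zipper" closure).  Trigonocephaly is
  modeled by tapering the frontal sectors toward a mid-sagittal ridge,
  parameterized by the interfrontal angle (physiologic 135°; synostosis
  presets 100.25° and 104.71°).

Hexahedral cells are subdivided into 24 tetrahedra through face and body
centroids.  This costs ~4× the element count of a minimal subdivision but
is unconditionally conforming across any node-shared interface (panel
seams, vault↔face junction) and commutes with mirror reflection, making
the mesh exactly symmetric about z = 0 — node positions to machine
precision, element regions by construction.  Default desk-scale meshes
(6 mm target edge) have ~105 k tetrahedra; generation is deterministic
(the `random_seed` parameter is provenance only; no jitter is applied by
default).

Mesh quality on the default and test geometries: positive volumes
everywhere, minimum dihedral angle above the 10° floor (the strongest
trigonocephalic taper presets can dip to ~9°, a consequence of shearing
the frontal sectors rather than remeshing them).

## Loading model

Muscle force magnitude = CSA (cm²) × specific tension 22.5 N/cm² × EMG
activation factor; direction = unit vector from the area-weighted centroid
of the muscle's cranial origin patch to a fixed mandibular insertion point
(the mandible is not meshed).  The resultant is distributed over the origin
patch by tributary facet area, all nodes loaded along the same direction.
Five muscles per side are modeled (deep/superficial masseter,
anterior/posterior temporalis, medial pterygoid); the lateral pterygoid is
omitted as a jaw opener.

* **Chewing (right working side)** — bilateral activation, right side at
  working EMG factors, left at balancing factors; right TMJ and bite point
  fixed in x, y, z; left TMJ in x, y.
* **Suckling** — bilateral suckling EMG factors with the medial pterygoid
  tied to the masseter ratio, plus −87 mmHg (−11 599 Pa) on the palate
  facets (negative pressure pulls along the outward normal); both TMJs and
  the midline latch point fixed.
* **Single-muscle-group cases** — one group active bilaterally at the
  working EMG factor under chewing constraints; a pressure-only case uses
  suckling constraints.

EMG activation factors are **flagged placeholders** (working: temporalis
and masseter 1.0, medial pterygoid 0.6; balancing 0.5×; suckling 0.4):
the source study's exact factors live in supplementary material that is not
reproduced here, so configs must override them for fidelity.  Default
infant CSAs (0.8/1.6/1.4/1.0/1.0 cm²) are plausible literature-scale
values.  The default chewing bite point is the right first molar ridge;
second-molar and lateral-incisor variants exist for sensitivity analysis.
The foramen magnum is unconstrained by default, with an optional
constraint for the boundary-condition sensitivity pair.

Attachment siting on a skull with no zygomatic arch deserves explicit
statement: the temporal fossa windows sit posterior to the coronal complex
and below the superior temporal line, with a near-vertical pull to the
coronoid; the masseter origins occupy the lower lateral rim band beneath
where the arch would run, pulling nearly vertically to the angle/ramus;
the medial pterygoid originates at the posterior palate edge (pterygoid
plate region) pulling infero-latero-posteriorly.  Muscles never attach on
suture surfaces.

## Numerics

* Assembly is vectorized per region; the global stiffness is symmetric
  sparse CSR over 3N displacement DOFs.
* Dirichlet constraints are eliminated by row/column reduction; prescribed
  values default to zero (nonzero values support the patch test).
* The solve is a sparse direct factorization (SuperLU); the relative
  residual must be < 1e-8 or the solve raises.  Reactions are recovered at
  constrained DOFs and global equilibrium (applied + reactions) is checked
  for every case.  A `CachedSolver` reuses one factorization across load
  cases that share a constraint pattern (the muscle decomposition).
* Strain recovery: constant element strains (B·u), volume-weighted
  averaging to nodes, principal values by symmetric eigendecomposition
  sorted descending.  Stress via isotropic Hooke's law per region; von
  Mises and Tresca from the standard invariants.
* Degenerate tetrahedra (|V| < 1e-12 mm³) are rejected at assembly.

## Suture analytics

Cross-suture (axial) strain is the normal component perpendicular to each
suture's main direction: ε_zz for nasofrontal/metopic/sagittal, ε_yy for
coronal, ε_xx for squamous, and for the lambdoid the larger-magnitude of
the suture-averaged ε_zz and ε_xx (the max rule is applied to the two
suture means, yielding one summary per suture; a per-node max was the
rejected alternative).  Statistics average nodal strain over the suture's
pooled endo- and ectocranial surface nodes; working (R) and balancing (L)
sides are summarized separately.  Cumulative shear is
|mean ε_xy| + |mean ε_xz| + |mean ε_yz| — magnitudes of the averages, not
averages of magnitudes, which a property test pins down via the triangle
inequality.  Mid-sagittal profiles map midline surface nodes to
θ = atan2(x, y) (0° anterior, 90° vertex) and bin at 2° anchored at zero;
nodes shared by adjacent midline sutures are assigned to exactly one suture
by a fixed priority partition.  Signed per-bin means are the default (a
magnitude flag exists).

## What the generator does and does not emulate

The synthetic calvarium reproduces the topology and relative compliance of
the infant vault — soft full-thickness sutures in a stiff shell, a face
that feeds masticatory loads into the anterior vault through the
nasofrontal band, a closable metopic strip — and is exactly
mirror-symmetric, deterministic, and parametric in closure state and
interfrontal angle.  It does **not** emulate patient-specific vault shape,
orbits, sinuses, tooth crypts, the zygomatic arch, suture interdigitation,
or any absolute anatomical fidelity of attachment footprints.  Passing
qualitative regressions therefore says the *mechanistic pattern* (which
sutures are tensed vs compressed, how strain redistributes as the metopic
closes) survives the idealization; it says nothing quantitative about
strain magnitudes in real infants, which depend on the unavailable
patient geometries.

Known limitation, stated rather than hidden: during suckling the lambdoid
sutures carry ~+4 με (marginal tension) where the patient-based study
reports compression.  With no occipital or nuchal loading and a
cartilage-decoupled occipital plate, nothing in this idealization
compresses the lambdoid under suckling loads; the corresponding sign
regression is reported as failing.  All other schematic signs (14/16
classified entries), the metopic closure trend, the midline profile
minima, and the shear ranking reproduce the study's patterns.

## Verification battery

* **Patch test** — affine boundary displacements on a tet-meshed cube
  reproduce the exact constant strain (< 1e-9 relative).
* **Lamé thick-walled sphere** (cubed-sphere shell, R 50→70 mm, internal
  pressure): mid-wall radial displacement error decreases monotonically
  over three refinements and is < 3 % at ~43 k elements.
* **Timoshenko cantilever** (80×8×8 mm prism, end shear load distributed
  over the tip face): tip deflection within 5 % of the shear-corrected
  closed form at the finest desk mesh (~35 k elements).
* **Equilibrium** — applied + reaction forces cancel to 1e-8 relative for
  every solved case; uniform pressure on a closed surface nets < 1e-9 N.
* **Superposition** — per-muscle-group chewing sub-fields sum to the full
  chewing field to < 1e-8 relative.
* **Determinism** — identical config + seed produces byte-identical
  summary CSVs.

Problem sizes (6 mm default calvarium, ~43 k element Lamé shell, ~35 k
element beam) are the package's desk-scale defaults: large enough for the
stated tolerances, small enough to run on a laptop in minutes.
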