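# Methods

This note documents the models behind clefscope, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that make runs reproducible.

## Structures, alignments and the matched-residue subset

All analyses are Cα-level.  A structure is an ordered list of
(chain, author res_id, one-letter code, xyz) tuples; author numbering is
kept verbatim so residue labels like W554 match the literature, user-facing
intervals are 1-based inclusive, and internal arrays are 0-based.  Insertion
codes are rejected outright — homology models do not carry them, and silent
renumbering would be worse than an error.  Alternate locations resolve to
the highest-occupancy (first on ties) conformer.  FASTA and Clustal MSAs are
accepted, with both `-` and `.` read as gaps; an `AlignmentMap` records
which residue occupies each column, and the *ungapped* columns (occupied in
every sequence) are the common coordinate frame for all family analyses.

When a full-length enzyme is compared with its CBM-truncated form, the
matched-residue ("corrected") subset of the full-length structure — its
residues at alignment columns occupied by both sequences — puts the two on
equal footing.  It is a pure column-set intersection; no coordinates are
altered.

## Superposition and the invariant core

Rigid superposition is least-squares (Kabsch), with the reflection branch
excluded; an independent quaternion-grid minimizer backs it in the test
suite.  Ensembles are superposed onto a reference member (the first, by
default) over a chosen fit-column set.

For each ungapped column, the population (1/n) covariance of the superposed
member positions defines an ellipsoid whose semi-axes are the square roots
of the three eigenvalues, so

    V = (4/3) π √(λ₁λ₂λ₃) = (4/3) π √det(Σ)   [Å³].

Population rather than sample covariance is a deliberate, documented choice:
the volumes are compared with each other and against a fixed cutoff, so
only the convention must be stable.  The invariant core is found by
iterative elimination: superpose on the current candidate set, compute all
column volumes, remove the single largest (ties → lowest column index, for
determinism), repeat until every surviving column is below the cutoff
(default 1.0 Å³) or a floor size (`min_core`) is reached.  Re-superposition
after every elimination is the default; a single initial superposition and
a total-volume stopping criterion are available as config switches
(`core.resuperpose`, `core.criterion`) because either reading of the
procedure is defensible.  Reported volumes are those of the final
iteration, for all ungapped columns.

## Elastic-network modes, RMSF and DCCM

The "generic force field" is realised as the standard anisotropic network
model: Hookean springs of stiffness γ (default 1, dimensionless) between Cα
pairs within a cutoff (default 15 Å, a common Cα-ANM choice).  The Hessian
superblocks are H_ij = −γ ddᵀ/|d|² on contacts, with diagonal blocks
closing the row sums to zero; the model is unweighted (no residue masses) —
mass-weighting would only rescale a spectrum that is already in arbitrary
units.  Frequencies are reported as ω = √λ in those arbitrary units;
absolute mode frequencies depend on γ and the cutoff and are not treated as
physical observables.  Eigenvalues below 1e-8·λ_max count as zero modes; a
connected structure has exactly six, and more than six aborts with a
disconnected-structure error rather than silently inverting a singular
spectrum.

Mode-derived fluctuations use the pseudo-inverse restricted to a
non-trivial mode window, default modes 7–18 (the low-frequency end that
carries domain-scale motion):

    rmsf_i = √(Σₖ λₖ⁻¹ |v_{k,i}|²),
    C_ij   = Σₖ λₖ⁻¹ v_{k,i}·v_{k,j} / √(⟨Δr_i²⟩⟨Δr_j²⟩).

Ensemble-derived counterparts use deviations from the frame mean of a
pre-superposed trajectory.  Both DCCM routes are provided because either a
mode basis or a trajectory can be the primary object in practice; the
analytic mode-space map and a map sampled from the mode distribution agree
to max |Δ| < 0.05 at 10⁵ frames in the acceptance checks.

## Interaction surfaces and buried area

Residue runs with concerted motion are read off the DCCM as rectangular
blocks of entries ≥ r_min between runs at least `min_separation` residues
apart in sequence.  Defaults r_min = 0.8, min_len = 4, min_separation = 10:
the criterion for "strongly correlated" in the literature is essentially
r ≈ 1, so 0.8 is a permissive screen whose value is recorded in every
output header and freely adjustable.  Blocks are grown from connected
components of the thresholded map, split at domain boundaries, and shrunk
greedily to full rectangles; segment pairs are classified by the domain
pair they join (GC, GL, CL), and a connected patch touching all three
domains is the composite class GLC.

Interface size is quantified as buried solvent-accessible surface area,
BSA = SASA(A) + SASA(B) − SASA(A∪B), with Shrake–Rupley quadrature on a
deterministic golden-angle spiral (960 points) and a *residue-sphere* model:
one sphere of radius 3.0 Å per Cα, probe 1.4 Å.  The sphere radius
approximates side-chain extent and keeps the method applicable to Cα-only
models; the absolute scale is therefore coarser than an all-atom SASA, and
BSA values should be compared within this model, not against all-atom
contact areas.  Whether published per-surface areas mean buried SASA or a
contact surface is ambiguous in general; buried SASA is used here and
labelled as such.

## Coordinate PCA and quadrant clustering

PCA is performed on the covariance (not correlation) of the flattened
3C-vectors of the superposed family — mean-centred, unscaled, which is the
standard convention for coordinate PCA.  At most S−1 components carry
variance for S members.  Component signs are fixed by making the
largest-magnitude loading positive; this makes runs reproducible but leaves
quadrant labels arbitrary up to reflection, which the Hungarian-matched
recovery metric in the tests is insensitive to.  Quadrant clustering labels
each member by the sign pair of two chosen component scores (zeros count as
positive); the axis pair is a parameter (default (1, 3); the synthetic
family's planted clusters separate on (1, 2)).  PCA can be restricted to
invariant-core columns (`--columns core`) when peripheral noise would
otherwise dominate.

## Groove geometry and the approximating cylinder

The cylinder model reduces a groove's observed area A_o and volume V_o to
r = √(A_o/4π), h = 4V_o/A_o, l = A_o/r, with recomputed A_c = 2πr(r+h),
V_c = πr²h and approximation constants ∅ = |A_o − A_c|, β = |V_o − V_c|.
Two identities follow algebraically: V_c = V_o (so β ≡ 0 for every input)
and l = 4πr.  The bundled reference table of 77 published (r, l) pairs
satisfies the second identity to ≤ 0.16 Å; 76 of the 77 rows fall within
0.15 Å and one row deviates by 0.153 Å, a rounding artefact of the printed
source values that is reported as-is rather than corrected.

Groove *measurement* uses a grid flood-fill: grid points (spacing
0.25–2.0 Å, default 0.5 Å) outside every probe-inflated residue sphere but
unreachable from the bounding-box boundary are pocket candidates; connected
components above a volume floor are reported with V_o = cells·spacing³ and
A_o = obstacle-facing faces·spacing².  The voxel-face estimator
overestimates smooth areas by up to ~1.5×; halving the spacing changes the
volume of a constructed 1000 Å³ test cavity by < 5%, and spacing refinement
is the recommended control when absolute areas matter.  Because the
detector is a stand-in for interactive surface tools, the cylinder model
also accepts (A_o, V_o) pairs directly, so published tables can be analysed
without any pocket detection.

## Active-site set algebra

Residue lists in `L60, Q64, …` notation are parsed strictly (valid
one-letter codes, unique residue numbers).  The consolidated active site is
Dock ∩ CvG; the expected containment within the interaction-surface set is
*reported* when violated, never enforced, since the violation itself is the
scientifically interesting event.  Composition classes are frozen as
AAA = {W,F,Y}, P, RKNQ, ST, HSC = {L,I,V,A,M}, CAT = {D,E,C,H}; S and T
count only in ST, the classes are disjoint, glycine is untracked, so the
six fractions sum to ≤ 1.  The bundled lists are ingested as the union of
docking-favourable and cavity-lining residues; the published typography
distinguishing the two subsets does not survive plain text, so the CvG
subset can be supplied as a side file but is never guessed.

## Synthetic data: what it emulates, what it does not

The generators produce the statistical structure the pipeline assumes, at
the canonical class C architecture: a compact ~450-residue GH9-like bead
cloud, a < 100-residue extended linker, and a ~110-residue CBM49-like
cloud (defaults 450/60/110; GH9 cloud radius 24 Å, CBM scaled by the cube
root of the residue ratio; every bead pair ≥ 3.5 Å).  Domains are bead
clouds, not folded chains — every analysis here consumes only Cα geometry,
so secondary structure would add nothing the methods can see.  The linker
is a 2 Å-radius spiral rather than a straight line, and the CBM envelops
the linker end, so the elastic network is well connected and has exactly
six zero modes.

Ensembles add per-domain isotropic Gaussian displacements (defaults
σ(GH9) = 0.3 Å, σ(L) = σ(CBM49) = 1.5 Å — a five-fold mobility excess of
linker+CBM over the catalytic core, the qualitative hallmark these enzymes
show) plus a random rigid motion per frame so superposition is always
exercised; 500 frames by default.  Families (default 40 members) plant a
rigid core (the GH9 columns, σ = 0.05 Å) against a variable periphery
(σ = 3 Å) and up to four clusters realised as 8 Å rigid CBM shifts along
the four xy-diagonals, which a PCA of the family separates into sign
quadrants of the two leading components.

Passing tests on these fixtures demonstrate that the algorithms recover
planted truth under idealised noise; they do not demonstrate robustness to
features real model families have and the generator lacks: correlated
(non-isotropic) noise, alignment gaps, partial domains, register shifts, or
sequence-dependent packing.  The bundled published tables cover the parts
of the pipeline that can be checked against real numbers (the cylinder
model and the residue-list statistics); the geometric and dynamic stages
are validated against closed forms and independent oracles instead.

All generators are pure functions of (spec, seed): one global seed feeds
named per-operation substreams (FNV-hashed), so adding a generator never
perturbs the draws of another, and repeated calls are bit-identical.

## Numerical conventions and limitations

* Zero-mode tolerance 1e-8·λ_max; DCCM symmetrised and clipped to [−1, 1]
  after normalisation; correlation maps validated to 1e-10.
* Tie-breaks: invariant-core elimination removes the lowest-index column on
  equal volumes; quadrant scores of exactly 0 count as positive.
* The pipeline is single-threaded and deterministic: identical config and
  seed reproduce identical output bytes.
* Study problem sizes used by the test-suite and the acceptance script:
  620-residue architecture, 40-member families, 500-frame ensembles,
  10⁵-frame mode-sampling checks on a 20-residue fixture — large enough
  for stable statistics at the planted effect sizes.
* Known limitations: no mmCIF or hetero-atom input; no all-atom NMA or MD;
  docking energetics are consumed as residue lists, never computed; the
  grid groove finder reports enclosed pockets (a probe-tight groove is
  found, an open shallow cleft is not); absolute SASA/BSA scales are
  residue-sphere-model quantities.
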