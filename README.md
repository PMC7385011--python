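# clefscope

Structural-dynamics analysis of multi-domain plant **class C GH9
endoglucanases** — enzymes built from a glycoside hydrolase family 9
catalytic domain (GH9, ~450 residues), a flexible linker (< 100 residues)
and a carbohydrate-binding module (CBM49, ~40–200 residues) that together
digest crystalline cellulose.  The package is aimed at structural
bioinformaticians who work with Cα-level homology models of such enzymes and
want a reproducible, scriptable version of the classic model-family
analyses: which parts of the fold are conserved, which parts move, where the
domains talk to each other, and what the substrate-binding groove looks
like.

Everything operates on Cα coordinates, so plain homology models are
sufficient input.

## What it computes

* **Ensemble superposition and invariant core** — least-squares (Kabsch)
  superposition over ungapped alignment columns; for each column the 3×3
  positional covariance across the family defines an ellipsoid of volume
  V = (4/3)π√(λ₁λ₂λ₃).  Columns are eliminated iteratively (largest volume
  first, re-superposing on the survivors) until all remaining volumes fall
  below a cutoff (default 1.0 Å³): the surviving set is the structurally
  invariant core.
* **Elastic-network normal modes** — anisotropic network model on the Cα
  trace (springs γ between pairs within 15 Å); eigenvalues λₖ, frequencies
  ω = √λ, exactly six zero modes for a connected structure, non-trivial
  modes indexed from 7.  Per-residue fluctuations
  rmsf_i = √(Σₖ λₖ⁻¹|v_{k,i}|²) over a mode window (default 7–18), with the
  spread scores Δrmsf = max − min and σ.
* **Dynamic cross-correlation maps** —
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩), from modes or from a superposed
  ensemble; symmetric, unit-diagonal, bounded in [−1, 1].
* **Interaction surfaces** — rectangular blocks of high positive
  correlation between sequence-separated residue runs, trimmed to single
  domains and classified GC / GL / CL (or GLC when one connected patch
  touches all three domains); each surface quantified by buried solvent-
  accessible area (Shrake–Rupley on a residue-sphere model).
* **Coordinate PCA and quadrant clustering** — PCA of flattened 3C-vectors
  over ungapped columns; families are grouped by the sign quadrant of two
  chosen component scores.
* **Groove geometry** — a grid flood-fill pocket finder, and the cylinder
  approximation of a groove with observed area A_o and volume V_o:

      r = √(A_o/4π),  h = 4V_o/A_o,  l = A_o/r,
      A_c = 2πr(r+h),  V_c = πr²h,  ∅ = |A_o−A_c|,  β = |V_o−V_c|

  with the built-in identities V_c ≡ V_o (β ≡ 0) and l ≡ 4πr.
* **Active-site set algebra** — residue lists like `L60, Q64, A67` combined
  as Dock ∩ CvG with an IS-containment report, plus amino-acid class
  composition (aromatic WFY, P, RKNQ, ST hydroxyl, LIVAM hydrophobic, DECH
  catalytic-type).
* **Synthetic data** — seeded generators for multi-domain structures,
  mobile-linker ensembles and structure families with planted cores and
  clusters, so the whole pipeline is testable without external data.

Reference tables for the four laboratory-characterised class C enzymes
(UniProt Q5NAT0, Q8LJP6, Q93WY9, Q9ZSP9) — groove observations, published
cylinder dimensions and candidate active-site residue lists — ship with the
package (`clefscope.datasets`).

## Worked example

```python
import numpy as np
from clefscope import (SyntheticSpec, make_multidomain_structure, make_family,
                       find_invariant_core, superpose_ensemble, coordinate_pca,
                       quadrant_cluster, compute_modes, mode_rmsf,
                       cylinder_from_groove)

spec = SyntheticSpec(n_gh9=60, n_linker=12, n_cbm=20, domain_radius=12.0,
                     n_members=8, seed=0)
structure, domains = make_multidomain_structure(spec)
members, core_truth, clusters, amap = make_family(structure, domains, spec)

core = find_invariant_core(members, amap, cutoff=1.0, min_core=20)
print(f"invariant core: {len(core.core_columns)}/{len(core.volumes)} columns "
      f"below {core.cutoff} A^3")

modes = compute_modes(structure)
prof = mode_rmsf(modes, (7, 18))
gh9 = np.array([domains.label_of(r.res_id) == "GH9" for r in structure.residues])
print(f"mode RMSF, linker+CBM vs GH9 core: "
      f"{prof.rmsf[~gh9].mean() / prof.rmsf[gh9].mean():.2f}x")

pca = coordinate_pca(superpose_ensemble(members, amap))
print("quadrants:", quadrant_cluster(pca, 1, 2))

c = cylinder_from_groove(905, 616)
print(f"groove cylinder: r={c.r:.2f} h={c.h:.2f} l={c.l:.2f} "
      f"A_c={c.A_c:.2f} V_c={c.V_c:.2f} dA={c.phi:.2f} dV={c.beta:.2f}")
```

prints

```
invariant core: 60/92 columns below 1.0 A^3
mode RMSF, linker+CBM vs GH9 core: 2.27x
quadrants: ['(+,+)', '(+,-)', '(-,+)', '(-,-)', '(+,+)', '(+,-)', '(-,+)', '(-,-)']
groove cylinder: r=8.49 h=2.72 l=106.64 A_c=597.67 V_c=616.00 dA=307.33 dV=0.00
```

The invariant core recovers exactly the 60 planted rigid (GH9) columns and
rejects the 32 mobile linker/CBM columns; the linker and CBM fluctuate more
than the catalytic core in the low-frequency modes; the eight family members
fall into the four planted sign-quadrant groups; and the groove of the rice
enzyme (A_o = 905 Å², V_o = 616 Å³) maps to a cylinder of radius 8.49 Å and
height 2.72 Å whose volume reproduces the observation exactly (dV = 0 — an
algebraic identity of the model).

The same analyses are available from the shell:

```
clefscope simulate family --seed 0 --out sim/
clefscope core --pdb-dir sim/family --msa sim/family.fasta --out core.tsv
clefscope nma --pdb sim/structure.pdb --modes 7:18 --out modes.tsv
clefscope cylinder --area 905 --volume 616
clefscope run --config cfg.yaml        # full pipeline
```

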