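# Methods

## Model and procedure

`consite` treats an interface analysis as five stages, each exposed as a
library function and composed by `analyze_complex` / `predict_binding_site`:

1. **Interface detection.** Solvent-accessible surface area is computed per
   atom by the Shrake–Rupley scheme (biotite backend, deterministic Fibonacci
   point distribution), with a probe radius of 1.4 Å, 960 sample points per
   atom and a per-element van der Waals radius table (C 1.70, N 1.55, O 1.52,
   S 1.80 Å, …; hydrogens are excluded along with waters and, by default,
   het-groups). A residue belongs to the interface if its summed atomic SASA
   drops by more than 0.1 Å² between the isolated chain group and the
   complex. The 0.1 Å² rule is applied at residue level (summed atomic
   ΔASA); atom coordinates are retained for the patch-radius rules, which
   operate on atoms.
2. **Conservation.** Alignment columns are mapped onto structure residues
   through the query row (exact match fast path; otherwise a global pairwise
   alignment that tolerates coordinate gaps and up to 5% identity
   mismatches). Column entropy uses natural logarithms over the 7 amino-acid
   classes; the base cancels in every selection criterion. Gaps and
   nonstandard codes are excluded from the counts; columns with fewer than 2
   usable rows are treated as undefined and dropped rather than reported as
   spuriously conserved. The relative-entropy variant sums p ln(p/p_back)
   over the classes observed in the column, without renormalising the
   background; backgrounds built from pooled sequences use one pseudo-count
   per class so the measure is always defined.
3. **Selection and clustering.** Conserved residues are selected per
   interface (or per patch) with a strict `<` against the mean (and SD) of
   that same residue set, or as exactly zero entropy (tolerance 1e-12); a
   1e-12-relative guard keeps values equal to the cutoff up to float error
   out of the strict comparisons. M_s uses residue centers of mass
   (mass-weighted heavy atoms). The randomisation test draws
   `n_random = 1000` subsets without replacement from a single seeded
   generator (default seed 20100527) and reports the anti-conservative
   estimator p = (1 + #{M_s,random ≥ M_s,cons}) / (n_random + 1), which can
   never return 0.
4. **Sub-clusters.** Average-linkage (UPGMA) agglomeration on residue
   centers, cut at 15 Å (complexes) or 21 Å (homodimers); because UPGMA
   merge heights are monotone, cutting the scipy dendrogram at the threshold
   is identical to merging while the minimum average inter-cluster distance
   stays at or below it (ties inclusive). The thresholds follow the rule
   "half the mean maximum inter-atom distance among conserved interface
   residues", which `derive_linkage_threshold` implements on atoms.
   Singleton clusters are legitimate outputs and count as clusters in
   hot-spot localization (a flag excludes them).
5. **Patches and ranking.** Surface residues are those with residue SASA ≥
   5% of a per-type reference maximal accessibility (extended-state
   reference table shipped with the package; a fixture-geometry reference is
   generated at run time for toy structures). Method 1 uses a fixed radius
   (15 Å complexes / 22 Å homodimers — half the typical maximum interface
   atom-pair distances of 30/44 Å); Method 2 halves the analyzed protein's
   own maximum interface atom-pair distance; Method 3 additionally requires
   the angle between the member's and the center's solvent vectors to be
   below 110°. The solvent vector of a residue is the unit vector opposite
   to the offset from the residue center to the centroid of its 10 nearest
   surface residues. Each patch is scored like an interface: conserved
   residues are selected against the patch's own entropy mean, and ρ is
   computed over the patch's scored residues. The true interface is scored
   as its own residue set, ranked by "1 + number of patches with strictly
   greater ρ" (optimistic tie-break), binned into deciles over patches +
   interface, and given Z = (ρ_int − ⟨ρ⟩)/σ over the numeric patch ρ values.
   Patches with fewer than 2 scored or 2 conserved residues carry an
   explicit too-few marker: they stay in the decile denominator but rank
   below every numeric ρ, on the view that a patch without a scorable
   conserved cluster is evidence against binding there.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| probe radius | 1.4 | Å | water-probe convention |
| SASA points/atom | 960 | – | ≈1% single-sphere accuracy, deterministic |
| burial threshold | 0.1 | Å² | interface membership rule |
| surface threshold | 0.05 | fraction | relative-accessibility cutoff |
| conservation criterion | below mean | – | least stringent of the three; the others tighten it |
| n_random | 1000 | subsets | resolution of the empirical p (~1e-3) |
| linkage threshold | 15 / 21 | Å | complexes / homodimers, half mean max atom distance |
| patch radius (Method 1) | 15 / 22 | Å | half typical interface diameter |
| solvent-vector angle | 110 | degrees | keeps patches on one molecular face |
| k nearest neighbours | 10 | residues | solvent-vector construction |

## Synthetic data: what it emulates and what it does not

The generator builds two-bead residues (backbone + side-chain carbon beads)
in two geometries. **Two-slab**: each chain is a 6.5 Å planar lattice; a
designed rectangular block bulges toward the partner so exactly the block
comes into 4.6 Å contact (inside the 6.2 Å carbon–carbon occlusion range at
probe 1.4 Å) while everything else stays ≥ 14 Å away — interface recovery by
ΔASA is exact by construction, with in-plane jitter (sd 0.25 Å) for
variability. **Sphere-contact**: Fibonacci shells touching pole-to-pole; the
polar cap of the stated size is the designated interface. Alignments give
planted-conserved columns zero class entropy and every other column an
independent class-entropy target (default ln 2 nats at depth 60), realised
by mixing the query's class with alternatives at a solved probability.
ΔΔG annotations plant an exact fraction of hot residues (ΔΔG ≥ 2 kcal/mol)
inside the conserved blobs.

These fixtures have no secondary structure, no rotamers, no packing
heterogeneity, no phylogenetic correlation between alignment rows, and no
correlation between conservation and residue type. Passing tests therefore
demonstrate that the statistics and the pipeline behave as specified under
controlled signal and null conditions — not that any particular biological
interface will score well; on real data the signal strength depends on
alignment quality and depth, and antibody–antigen interfaces in particular
are poor candidates for conservation-based analysis.

## Study conditions of the shipped ensembles

The acceptance script and the ensemble tests run at sizes chosen to give
stable rates on a single CPU in minutes: 200 fixtures per placement for the
clustered/scattered ρ ensembles (96 residues/chain, 16-residue interface, 4
conserved); 100 seeds per condition for sub-cluster recovery (60-residue
interface, k = 1..3 blobs of 5 fully-conserved residues at block corners
separated by > 30 Å = 2× the 15 Å threshold, zero-entropy criterion so the
planted set is recovered exactly); 50 seeds per patch method for ranking
recovery (240-residue sphere, 20-residue cap whose ~30 Å atom-pair diameter
matches the fixed 15 Å patch radius, so all three methods face comparable
geometry). Seeds for each fixture are spawned deterministically from one
master seed.

## Numerical choices and degenerate inputs

- Natural log everywhere; criteria compare s(i) to its own mean, so the base
  is immaterial.
- Coincident residue centers raise an error rather than produce infinite
  inverse distances.
- Fewer than 2 points (M_s) or 2 conserved residues (ρ) raise distinct
  signal exceptions; patch scoring converts them into the too-few marker.
- A Z-score over patches with zero ρ variance is reported as NaN.
- Reports are serialised with sorted keys, rounded to 10 decimals and no
  timestamps, so identical (input, config, seed) reruns are byte-identical;
  every report carries a hash of its configuration.

## Design choices that were genuinely open

- **Per-chain analysis.** The conserved set, ρ, the randomisation test and
  the sub-clustering are computed over the interface residues of one
  analyzed chain (the first chain of group A by default), the chain the
  alignment belongs to. Homodimers are analysed on a single subunit.
- **Solvent vectors on flat or rim regions.** The 10-neighbour centroid
  construction gives clean anti-parallel vectors on opposite faces of a
  slab, but at the rim the faces merge and vectors turn sideways; face
  separation is therefore a claim about interior residues. On quasi-uniform
  lattices the vectors can tilt tens of degrees from the ideal normal
  (neighbour-set anisotropy), which is why the membership rule uses the
  lenient 110° cutoff.
- **Adaptive patch radii** (Methods 2–3) are derived from the analyzed
  chain's own interface atoms, and in prediction mode (no known interface)
  must be supplied explicitly.
- **Decile denominator** includes the interface itself along with all
  patches.
- **Zero-entropy criterion for the sub-cluster ensemble.** The below-mean
  criterion occasionally admits a borderline noise column whose stray
  residue would appear as an extra singleton; the fully-conserved criterion
  isolates exactly the planted blobs and makes "recovered cluster count"
  a sharp question about the clustering machinery.

## Known limitations

- No biological-assembly reconstruction, no mmCIF requirement, first model
  of multi-model files only (selectable).
- No alignment building or weighting: the user supplies the MSA; redundant
  rows bias p(k) exactly as they would in the source alignments.
- The enrichment table is per-interface; dataset-scale statistics are left
  to the user to aggregate over many runs.
- Surface patches approximate interfaces as roughly circular regions;
  strongly non-convex or multi-patch interfaces will depress the attainable
  overlap and rank.
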