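"""Seeded simulation ensembles that characterise the method on synthetic complexes.

Each function runs the full relevant pipeline on generated fixtures under the
package's standard study conditions and returns summary rates.  The same
ensembles back the acceptance checks and the reproduction script, so the
numbers they report are always recomputed from scratch.

Study conditions (chosen once; see docs/methods.md):

- clustered/scattered ρ ensembles: two-slab complexes, 96 residues/chain,
  16-residue interface, 4 conserved residues (tight central blob or uniform
  over the interface), alignment depth 60, noise entropy ln 2, below-mean
  criterion, 1000-subset randomisation test.
- sub-cluster recovery: two-slab complexes, 192 residues/chain, 60-residue
  interface, k = 1..3 planted blobs of 5 conserved residues at
  well-separated block corners (blob separation > 30 Å = 2 × the 15 Å
  average-linkage threshold), zero-entropy criterion.
- binding-site ranking: sphere-shell chains of 240 residues with a
  20-residue contact cap (maximum atom-pair distance ≈ 30 Å, matching the
  15 Å fixed patch radius), 5 conserved residues clustered at the cap pole.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .structure import ResidueKey
from .conservation import entropy_profile, map_query_to_structure, select_conserved
from .cluster import (
    PointSet,
    average_linkage_subclusters,
    derive_linkage_threshold,
)
from .synthetic import (
    FixtureSpec,
    fixture_reference_table,
    make_alignment,
    make_complex,
    make_hotspot_annotations,
    make_thick_slab,
)
from .workbench import analyze_complex, predict_binding_site
from .patches import compute_solvent_vectors, generate_patches_vector
from .structure import surface_residues

CLUSTERED_SPEC = FixtureSpec(
    n_residues_per_chain=96, interface_size=16, conserved_fraction=0.25,
    placement="clustered", geometry="two-slab",
)
SCATTERED_SPEC = replace(CLUSTERED_SPEC, placement="scattered")
SUBCLUSTER_BLOB_SIZE = 5
SUBCLUSTER_SPEC = FixtureSpec(
    n_residues_per_chain=192, interface_size=60, conserved_fraction=5 / 60,
    placement="clustered", geometry="two-slab",
)
RANKING_SPEC = FixtureSpec(
    n_residues_per_chain=240, interface_size=20, conserved_fraction=0.25,
    placement="clustered", geometry="sphere-contact",
)
SUBCLUSTER_THRESHOLD = 15.0


def spawn_seeds(master_seed: int, n: int, stream: int) -> list[int]:
    """Deterministic per-fixture seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def clustering_ensemble(
    placement: str, n_fixtures: int, master_seed: int, n_random: int = 1000
) -> dict:
    """ρ and random-subset p for an ensemble of planted two-slab interfaces.

    ``placement='clustered'`` plants a tight conserved blob (the signal
    condition); ``'scattered'`` draws the conserved residues uniformly over
    the interface (the null condition).
    """
    base = CLUSTERED_SPEC if placement == "clustered" else SCATTERED_SPEC
    seeds = spawn_seeds(master_seed, n_fixtures, stream=1 if placement == "clustered" else 2)
    rhos, pvalues = [], []
    for seed in seeds:
        spec = replace(base, seed=seed)
        model, truth = make_complex(spec)
        alignment = make_alignment(spec, truth, model.subset(["A"]))
        report = analyze_complex(
            model, alignment, ["A"], ["B"],
            flavor="complex", criterion="mean",
            n_random=n_random, seed=seed,
        )
        rhos.append(report.clustering.rho)
        pvalues.append(report.random_test.p_empirical)
    rhos = np.asarray(rhos)
    pvalues = np.asarray(pvalues)
    return {
        "n": n_fixtures,
        "rhos": rhos,
        "pvalues": pvalues,
        "frac_rho_gt_1": float(np.mean(rhos > 1.0)),
        "mean_rho": float(rhos.mean()),
        "frac_p_lt_05": float(np.mean(pvalues < 0.05)),
    }


def subcluster_recovery(
    cluster_count: int, n_seeds: int, master_seed: int,
    threshold: float = SUBCLUSTER_THRESHOLD,
) -> dict:
    """Fraction of fixtures whose planted blob count is recovered exactly.

    Conserved residues are selected through the alignment with the
    zero-entropy (fully conserved) criterion and partitioned by
    average-linkage clustering at the given threshold.
    """
    base = replace(
        SUBCLUSTER_SPEC,
        conserved_fraction=SUBCLUSTER_BLOB_SIZE * cluster_count / SUBCLUSTER_SPEC.interface_size,
        cluster_count=cluster_count,
    )
    seeds = spawn_seeds(master_seed, n_seeds, stream=10 + cluster_count)
    exact = 0
    for seed in seeds:
        spec = replace(base, seed=seed)
        model, truth = make_complex(spec)
        chain = model.subset(["A"])
        alignment = make_alignment(spec, truth, chain)
        cmap = map_query_to_structure(alignment, chain, "A")
        profile = entropy_profile(alignment, cmap)
        conserved = select_conserved(
            profile, sorted(truth.true_interface["A"]), criterion="zero"
        )
        centers = model.residue_centers(conserved.members)
        partition = average_linkage_subclusters(PointSet.from_centers(centers), threshold)
        exact += partition.n_clusters == cluster_count
    return {"n": n_seeds, "frac_exact": exact / n_seeds}


def ranking_ensemble(method: int, n_seeds: int, master_seed: int) -> dict:
    """Fraction of single-chain sphere fixtures whose true interface lands in
    decile 1 of the surface-patch ρ ranking, for one patch method."""
    reference = fixture_reference_table()
    seeds = spawn_seeds(master_seed, n_seeds, stream=20 + method)
    deciles = []
    for seed in seeds:
        spec = replace(RANKING_SPEC, seed=seed)
        model, truth = make_complex(spec)
        alignment = make_alignment(spec, truth, model.subset(["A"]))
        ranking = predict_binding_site(
            model, alignment, "A", method=method, flavor="complex",
            reference_table=reference,
            true_interface=truth.true_interface["A"],
        )
        deciles.append(ranking.decile)
    deciles = np.asarray(deciles)
    return {
        "n": n_seeds,
        "deciles": deciles,
        "frac_decile_1": float(np.mean(deciles == 1)),
    }


def farface_violations(
    seed: int, nx: int = 8, ny: int = 8, thickness: float = 8.0, radius: float = 15.0
) -> dict:
    """Count solvent-vector-rule violations on a two-layer slab.

    The patch radius exceeds the slab thickness, so the plain distance
    criterion would pull in far-face residues; the 110° angle constraint must
    exclude every one of them.  Face separation is asserted between interior
    residues (clean anti-parallel vectors); at the slab rim the two faces
    merge and the vectors legitimately turn sideways.
    """
    model, layers = make_thick_slab(nx=nx, ny=ny, thickness=thickness, seed=seed)
    reference = fixture_reference_table()
    surface = surface_residues(model, reference_table=reference)
    centers = model.residue_centers()
    xy = np.array([c[:2] for c in centers.values()])
    lo, hi = xy.min(axis=0) + 7.0, xy.max(axis=0) - 7.0
    interior = {
        k for k, c in centers.items() if np.all(c[:2] > lo) and np.all(c[:2] < hi)
    }
    patches = generate_patches_vector(surface, centers, radius)
    vectors = compute_solvent_vectors(surface, centers)
    violations = 0
    cross_face = 0
    for patch in patches:
        v_c = vectors[patch.center].direction
        for member in patch.members:
            if member == patch.center:
                continue
            cos = float(np.dot(v_c, vectors[member].direction))
            if cos <= np.cos(np.radians(110.0)):
                violations += 1
            if (
                patch.center in interior
                and member in interior
                and layers[member] != layers[patch.center]
            ):
                cross_face += 1
    return {
        "n_patches": len(patches),
        "angle_violations": violations,
        "cross_face_members": cross_face,
    }


def hotspot_closure(master_seed: int, inside_fraction: float = 0.6, n_hot: int = 10) -> dict:
    """End-to-end hot-spot localization on a fixture with a planted in-cluster fraction."""
    spec = replace(
        SUBCLUSTER_SPEC,
        conserved_fraction=2 * SUBCLUSTER_BLOB_SIZE / SUBCLUSTER_SPEC.interface_size,
        cluster_count=2,
        seed=spawn_seeds(master_seed, 1, stream=30)[0],
    )
    model, truth = make_complex(spec)
    alignment = make_alignment(spec, truth, model.subset(["A"]))
    annotations = make_hotspot_annotations(
        truth, inside_fraction=inside_fraction, n_hot=n_hot, seed=spec.seed
    )
    report = analyze_complex(
        model, alignment, ["A"], ["B"],
        flavor="complex", criterion="zero", annotations=annotations,
        seed=spec.seed,
    )
    result = report.hotspots[2.0]
    return {
        "planted_fraction": round(inside_fraction * n_hot) / n_hot,
        "n_hot": result[1],
        "n_in_clusters": result[2],
        "fraction": result[3],
    }


def linkage_threshold_demo() -> float:
    """The threshold-derivation rule on two interfaces with maximum inter-atom
    distances of 40 and 44 Å (the homodimer scale): half the mean maximum."""
    seg_40 = np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0], [20.0, 3.0, 0.0]])
    seg_44 = np.array([[0.0, 0.0, 0.0], [0.0, 44.0, 0.0], [5.0, 20.0, 0.0]])
    return derive_linkage_threshold([seg_40, seg_44])
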