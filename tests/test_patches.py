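"""Surface patches: generation (Methods 1-3), solvent vectors, scoring and ranking."""

import math

import numpy as np
import pytest

from consite.conservation import EntropyProfile
from consite.patches import (
    SurfacePatch,
    adaptive_patch_radius,
    compute_solvent_vectors,
    generate_patches_adaptive,
    generate_patches_fixed,
    generate_patches_vector,
    patch_overlap_percent,
    rank_interface,
    score_patches,
    score_residue_set,
)
from consite.structure import ResidueKey, SurfaceSet
from consite.synthetic import make_thick_slab


def _surface(centers):
    return SurfaceSet(
        members=set(centers), relative_accessibility={k: 1.0 for k in centers}
    )


def _sphere_centers(n=80, radius=16.0):
    i = np.arange(n)
    golden = math.pi * (3 - math.sqrt(5))
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z * z)
    coords = radius * np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])
    return {ResidueKey("A", k + 1, ""): coords[k] for k in range(n)}


class TestFixedPatches:
    def test_isolated_residue_patch_of_one(self):
        centers = {
            ResidueKey("A", 1, ""): np.zeros(3),
            ResidueKey("A", 2, ""): np.array([100.0, 0, 0]),
        }
        patches = generate_patches_fixed(_surface(centers), centers, radius=15.0)
        by_center = {p.center: p for p in patches}
        assert by_center[ResidueKey("A", 1, "")].members == {ResidueKey("A", 1, "")}

    def test_radius_beyond_diameter_gives_whole_surface(self):
        centers = _sphere_centers()
        patches = generate_patches_fixed(_surface(centers), centers, radius=1000.0)
        for p in patches:
            assert p.members == set(centers)

    def test_brute_force_distance_filter(self):
        centers = _sphere_centers()
        patches = generate_patches_fixed(_surface(centers), centers, radius=15.0)
        for p in patches:
            expected = {
                k
                for k, c in centers.items()
                if np.linalg.norm(c - centers[p.center]) <= 15.0
            }
            assert p.members == expected

    def test_one_patch_per_surface_residue(self):
        centers = _sphere_centers()
        patches = generate_patches_fixed(_surface(centers), centers, radius=12.0)
        assert sorted(p.center for p in patches) == sorted(centers)


class TestAdaptiveRadius:
    @pytest.mark.parametrize("max_dist,expected", [(30.0, 15.0), (44.0, 22.0)])
    def test_halving_rule(self, max_dist, expected):
        atoms = np.array([[0.0, 0, 0], [max_dist, 0, 0], [5.0, 3.0, 0]])
        assert adaptive_patch_radius(atoms) == pytest.approx(expected, abs=1e-12)

    def test_equivalence_with_fixed_at_derived_radius(self):
        centers = _sphere_centers()
        atoms = np.array([[0.0, 0, 0], [26.0, 0, 0]])
        adaptive = generate_patches_adaptive(_surface(centers), centers, atoms)
        fixed = generate_patches_fixed(_surface(centers), centers, radius=13.0)
        assert [(p.center, p.members) for p in adaptive] == [
            (p.center, p.members) for p in fixed
        ]

    def test_degenerate_interface_raises(self):
        with pytest.raises(ValueError):
            adaptive_patch_radius(np.zeros((1, 3)))


class TestSolventVectors:
    def test_dense_sphere_vectors_are_radial(self):
        # shell where the 10 neighbours subtend substantial curvature: the
        # centroid sits well below the surface and the vector is near-radial
        centers = _sphere_centers(n=24, radius=10.0)
        vectors = compute_solvent_vectors(_surface(centers), centers)
        for key, c in centers.items():
            radial = c / np.linalg.norm(c)
            cos = float(np.dot(vectors[key].direction, radial))
            assert math.degrees(math.acos(np.clip(cos, -1, 1))) < 15.0

    def test_vectors_always_point_outward(self):
        # on finer shells lattice anisotropy tilts the vectors, but they must
        # always keep a positive outward (radial) component
        centers = _sphere_centers(n=120, radius=18.0)
        vectors = compute_solvent_vectors(_surface(centers), centers)
        for key, c in centers.items():
            radial = c / np.linalg.norm(c)
            assert float(np.dot(vectors[key].direction, radial)) > 0.0

    def test_symmetric_ring_gives_axis_direction(self):
        keys = [ResidueKey("A", i + 1, "") for i in range(11)]
        centers = {keys[0]: np.array([0.0, 0.0, 2.0])}
        for i in range(10):
            a = 2 * math.pi * i / 10
            centers[keys[i + 1]] = np.array([5 * math.cos(a), 5 * math.sin(a), 0.0])
        vectors = compute_solvent_vectors(_surface(centers), centers, k_neighbors=10)
        np.testing.assert_allclose(vectors[keys[0]].direction, [0, 0, 1], atol=1e-9)

    def test_unit_norm_contract(self):
        centers = _sphere_centers(n=40)
        vectors = compute_solvent_vectors(_surface(centers), centers)
        for v in vectors.values():
            assert np.linalg.norm(v.direction) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_neighbors_raises(self):
        centers = {ResidueKey("A", i + 1, ""): np.array([i * 5.0, 0, 0]) for i in range(5)}
        with pytest.raises(ValueError):
            compute_solvent_vectors(_surface(centers), centers, k_neighbors=10)


class TestVectorPatches:
    def test_far_face_of_slab_excluded(self):
        # the patch radius (15 Å) exceeds the slab thickness (8 Å), so the
        # plain distance rule would reach the opposite face; the angle rule
        # must keep the two faces apart.  At the slab rim the faces merge and
        # the solvent vectors turn sideways, so the face-separation claim is
        # made for interior residues (vectors cleanly anti-parallel).
        model, layers = make_thick_slab(nx=8, ny=8, thickness=8.0, seed=1)
        centers = model.residue_centers()
        xy = np.array([c[:2] for c in centers.values()])
        lo, hi = xy.min(axis=0) + 7.0, xy.max(axis=0) - 7.0
        interior = {
            k for k, c in centers.items()
            if np.all(c[:2] > lo) and np.all(c[:2] < hi)
        }
        surface = _surface(centers)
        patches = generate_patches_vector(surface, centers, radius=15.0)
        vectors = compute_solvent_vectors(surface, centers)
        cos_cut = math.cos(math.radians(110.0))
        crossings = 0
        for p in patches:
            for member in p.members - {p.center}:
                cos = float(
                    np.dot(vectors[p.center].direction, vectors[member].direction)
                )
                assert cos > cos_cut
            if p.center in interior:
                crossings += sum(
                    1 for m in p.members
                    if m in interior and layers[m] != layers[p.center]
                )
        assert crossings == 0

    def test_convex_cap_equals_distance_patches(self):
        # coarse shell: every solvent vector is within ~15° of radial and the
        # patch radius keeps central angles small, so the 110° filter passes
        # everything the distance rule admits and Method 3 equals Method 2
        centers = _sphere_centers(n=24, radius=10.0)
        surface = _surface(centers)
        vector_patches = generate_patches_vector(surface, centers, radius=9.0)
        fixed_patches = generate_patches_fixed(surface, centers, radius=9.0)
        assert {p.center: p.members for p in vector_patches} == {
            p.center: p.members for p in fixed_patches
        }

    def test_method_membership_nesting(self):
        centers = _sphere_centers(n=150, radius=20.0)
        surface = _surface(centers)
        radius = 14.0
        m1 = {p.center: p.members for p in generate_patches_fixed(surface, centers, radius)}
        m2 = {
            p.center: p.members
            for p in generate_patches_adaptive(
                surface, centers, np.array([[0.0, 0, 0], [2 * radius, 0, 0]])
            )
        }
        m3 = {
            p.center: p.members
            for p in generate_patches_vector(surface, centers, radius)
        }
        for center in centers:
            assert m3[center] <= m2[center] <= m1[center]

    def test_brute_force_distance_and_angle_filter(self):
        centers = _sphere_centers(n=100, radius=15.0)
        surface = _surface(centers)
        vectors = compute_solvent_vectors(surface, centers)
        patches = generate_patches_vector(surface, centers, radius=13.0)
        cos_cut = math.cos(math.radians(110.0))
        for p in patches:
            expected = {
                k
                for k, c in centers.items()
                if np.linalg.norm(c - centers[p.center]) <= 13.0
                and float(np.dot(vectors[p.center].direction, vectors[k].direction)) > cos_cut
            } | {p.center}
            assert p.members == expected


def _profile_from(values):
    keys = list(values)
    return EntropyProfile(values=dict(values), n_effective={k: 10 for k in keys})


class TestScoring:
    def test_fully_conserved_patch_has_unit_rho(self):
        centers = _sphere_centers(n=20, radius=10.0)
        profile = _profile_from({k: 0.0 for k in centers})
        patch = score_residue_set(set(centers), profile, centers, criterion="zero")
        assert patch.rho == 1.0
        assert patch.n_conserved == len(centers)

    def test_single_conserved_residue_yields_marker(self):
        centers = _sphere_centers(n=12, radius=10.0)
        keys = sorted(centers)
        values = {k: 1.0 for k in keys}
        values[keys[0]] = 0.0
        patch = score_residue_set(set(keys), _profile_from(values), centers, criterion="zero")
        assert patch.rho is None and patch.too_few
        assert patch.n_conserved == 1

    def test_undefined_entropy_residues_are_dropped(self):
        centers = _sphere_centers(n=10, radius=10.0)
        keys = sorted(centers)
        values = {k: float(i % 3) for i, k in enumerate(keys[:-2])}  # last 2 undefined
        patch = score_residue_set(set(keys), _profile_from(values), centers)
        assert patch.n_scored == len(keys) - 2

    def test_scores_match_independent_recomputation(self, m_s_oracle):
        rng = np.random.default_rng(31)
        centers = _sphere_centers(n=60, radius=15.0)
        keys = sorted(centers)
        values = {k: float(v) for k, v in zip(keys, rng.uniform(0, 1.5, len(keys)))}
        profile = _profile_from(values)
        patches = generate_patches_fixed(_surface(centers), centers, radius=12.0)
        for patch in score_patches(patches, profile, centers, criterion="mean"):
            members = sorted(patch.members)
            s = np.array([values[k] for k in members])
            conserved = [k for k, v in zip(members, s) if v < s.mean()]
            if len(members) < 2 or len(conserved) < 2:
                assert patch.rho is None
                continue
            expected = m_s_oracle(
                np.array([centers[k] for k in conserved])
            ) / m_s_oracle(np.array([centers[k] for k in members]))
            assert patch.rho == pytest.approx(expected, rel=1e-12)


def _patch(rho, n, center_id=1):
    members = frozenset(ResidueKey("P", center_id * 100 + i, "") for i in range(n))
    return SurfacePatch(
        center=ResidueKey("P", center_id * 100, ""), members=members, rho=rho,
        n_scored=n, n_conserved=max(2, n // 2),
    )


class TestRanking:
    def test_interface_on_top(self):
        patches = [_patch(0.8 + 0.02 * i, 5, i + 1) for i in range(12)]
        interface = _patch(1.5, 6, 99)
        ranking = rank_interface(patches, interface)
        assert ranking.interface_rank == 1
        assert ranking.decile == 1

    def test_z_score_arithmetic(self):
        patches = [_patch(0.9, 5, 1), _patch(1.1, 5, 2)]  # mean 1.0, population SD 0.1
        interface = _patch(1.3, 6, 9)
        ranking = rank_interface(patches, interface)
        assert ranking.z_score == pytest.approx(3.0, abs=1e-12)

    def test_rank_matches_brute_force_sort(self):
        rng = np.random.default_rng(32)
        for rep in range(20):
            rhos = rng.uniform(0.5, 1.8, size=99)
            patches = [_patch(float(r), 5, i + 1) for i, r in enumerate(rhos)]
            rho_int = float(rng.uniform(0.5, 1.8))
            interface = _patch(rho_int, 6, 999)
            ranking = rank_interface(patches, interface)
            expected_rank = 1 + int(np.sum(rhos > rho_int))
            assert ranking.interface_rank == expected_rank
            assert ranking.decile == math.ceil(10 * expected_rank / 100)

    def test_order_invariance(self):
        rng = np.random.default_rng(33)
        patches = [_patch(float(r), 5, i + 1) for i, r in enumerate(rng.uniform(0.5, 2, 30))]
        interface = _patch(1.2, 6, 999)
        base = rank_interface(patches, interface)
        shuffled = [patches[i] for i in rng.permutation(30)]
        other = rank_interface(shuffled, interface)
        assert (base.interface_rank, base.decile, base.z_score) == (
            other.interface_rank, other.decile, other.z_score,
        )

    def test_marker_patches_rank_last(self):
        patches = [_patch(0.8, 5, 1), _patch(None, 5, 2), _patch(1.2, 5, 3)]
        interface = _patch(1.0, 6, 9)
        ranking = rank_interface(patches, interface)
        assert ranking.interface_rank == 2  # only the 1.2 patch beats it
        assert ranking.patches[-1].rho is None

    def test_unscorable_interface_flagged_worst(self):
        patches = [_patch(0.8, 5, 1), _patch(1.2, 5, 2)]
        interface = _patch(None, 6, 9)
        ranking = rank_interface(patches, interface)
        assert ranking.interface_too_few
        assert ranking.decile == 10


class TestNullRankingCalibration:
    def test_deciles_uniform_without_conservation_signal(self):
        """With no planted conservation anywhere, the true interface is just
        another surface region: its decile over seeded replicates must be
        consistent with uniform (chi-square, alpha = 0.01)."""
        from dataclasses import replace

        from scipy.stats import chisquare

        from consite.synthetic import (
            FixtureSpec,
            fixture_reference_table,
            make_alignment,
            make_complex,
        )
        from consite.workbench import predict_binding_site

        reference = fixture_reference_table()
        deciles = []
        for seed in range(200):
            spec = FixtureSpec(
                geometry="sphere-contact", n_residues_per_chain=240,
                interface_size=20, seed=seed,
            )
            model, truth = make_complex(spec)
            null_truth = replace(truth, true_conserved=set(), true_subclusters=[])
            alignment = make_alignment(spec, null_truth, model.subset(["A"]))
            ranking = predict_binding_site(
                model, alignment, "A", method=2, reference_table=reference,
                true_interface=truth.true_interface["A"],
            )
            deciles.append(ranking.decile)
        counts = np.bincount(np.array(deciles), minlength=11)[1:]
        assert chisquare(counts).pvalue > 0.01


class TestOverlap:
    def test_reference_cases(self):
        interface = {ResidueKey("A", i, "") for i in range(10)}
        same = SurfacePatch(center=None, members=frozenset(interface))
        assert patch_overlap_percent(same, interface) == 100.0
        disjoint = SurfacePatch(
            center=None, members=frozenset({ResidueKey("B", 1, "")})
        )
        assert patch_overlap_percent(disjoint, interface) == 0.0
        half = SurfacePatch(
            center=None,
            members=frozenset({ResidueKey("A", i, "") for i in range(5)}),
        )
        assert patch_overlap_percent(half, interface) == 50.0

    def test_empty_interface_raises(self):
        with pytest.raises(ValueError):
            patch_overlap_percent(_patch(1.0, 3), set())
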