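"""Surface patch generation, scoring and interface ranking.

Overlapping, roughly interface-sized patches of surface residues are built
around every surface residue and scored by the clustering ratio ρ of their
own conserved residues.  Three constructions of increasing geometric care:

- Method 1: all surface residues whose centers of mass lie within a fixed
  radius of the central residue (defaults 15 Å for complexes, 22 Å for
  homodimers — half the typical maximum interface diameters of 30/44 Å).
- Method 2: as Method 1 but with a per-protein radius, half the maximum
  inter-atom distance of the true interface.
- Method 3: as Method 2, additionally requiring the angle between the
  'solvent vectors' of the member and central residues to be < 110°, which
  keeps a patch on one face of the molecule.

The true interface is scored by the same machinery and ranked among all
patches by descending ρ; the rank is reported as a decile (1 = top 10%)
together with a Z-score, Z = (ρ_int - <ρ>)/σ over the patch ρ values
(critical value 1.64, the normal 95th percentile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .structure import ResidueKey, StructureModel, SurfaceSet
from .conservation import EntropyProfile, select_conserved
from .cluster import (
    PointSet,
    TooFewConservedError,
    TooFewPointsError,
    clustering_ratio,
)

#: Fixed patch radii (Å) by analysis flavor (Method 1).
PATCH_RADII = {"complex": 15.0, "homodimer": 22.0}

DEFAULT_ANGLE_CUTOFF = 110.0
DEFAULT_K_NEIGHBORS = 10


@dataclass(frozen=True)
class SolventVector:
    """Unit vector pointing from a surface residue into the solvent."""

    residue: ResidueKey
    direction: np.ndarray


@dataclass
class SurfacePatch:
    """A contiguous set of surface residues centred on one residue.

    ``rho`` is None when the patch could not be scored (fewer than 2 scored
    residues or fewer than 2 conserved residues — the 'too few conserved'
    marker); such patches rank below all numerically scored ones.
    """

    center: ResidueKey | None
    members: frozenset[ResidueKey]
    rho: float | None = None
    n_scored: int = 0
    n_conserved: int = 0

    @property
    def too_few(self) -> bool:
        return self.rho is None


def _surface_arrays(surface_keys, centers):
    keys = sorted(surface_keys)
    coords = np.array([centers[k] for k in keys])
    return keys, coords


def generate_patches_fixed(
    surface: SurfaceSet,
    centers: Mapping[ResidueKey, np.ndarray],
    radius: float,
) -> list[SurfacePatch]:
    """Method 1: one patch per surface residue; membership by center-of-mass
    distance ≤ ``radius`` from the central residue."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    keys, coords = _surface_arrays(surface.members, centers)
    d = cdist(coords, coords)
    patches = []
    for i, key in enumerate(keys):
        members = frozenset(keys[j] for j in np.nonzero(d[i] <= radius)[0])
        patches.append(SurfacePatch(center=key, members=members))
    return patches


def adaptive_patch_radius(interface_atom_coords: np.ndarray) -> float:
    """Per-protein radius: half the maximum distance between any two atoms of
    the true interface."""
    coords = np.asarray(interface_atom_coords, dtype=float).reshape(-1, 3)
    if len(coords) < 2:
        raise ValueError("interface needs at least 2 atoms for the adaptive radius")
    return 0.5 * float(pdist(coords).max())


def interface_atom_coords(
    model: StructureModel, interface_keys: Iterable[ResidueKey]
) -> np.ndarray:
    """Coordinates of all atoms belonging to the given interface residues."""
    idx: list[int] = []
    for key in interface_keys:
        idx.extend(model.residue_atom_indices(key))
    if not idx:
        raise ValueError("no atoms found for the interface residues")
    return np.asarray(model.array.coord[idx], dtype=float)


def generate_patches_adaptive(
    surface: SurfaceSet,
    centers: Mapping[ResidueKey, np.ndarray],
    interface_atom_coords: np.ndarray,
) -> list[SurfacePatch]:
    """Method 2: fixed-radius construction at the per-protein adaptive radius."""
    return generate_patches_fixed(surface, centers, adaptive_patch_radius(interface_atom_coords))


def compute_solvent_vectors(
    surface: SurfaceSet,
    centers: Mapping[ResidueKey, np.ndarray],
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> dict[ResidueKey, SolventVector]:
    """Solvent vector of every surface residue.

    The centroid of the residue's ``k_neighbors`` nearest surface neighbours
    is computed; the solvent vector is the unit vector opposite to
    residue → centroid, i.e. pointing through the residue into the solvent.
    """
    keys, coords = _surface_arrays(surface.members, centers)
    n = len(keys)
    if n - 1 < k_neighbors:
        raise ValueError(
            f"need at least {k_neighbors} other surface residues, have {n - 1}"
        )
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    vectors: dict[ResidueKey, SolventVector] = {}
    for i, key in enumerate(keys):
        nearest = np.argsort(d[i], kind="stable")[:k_neighbors]
        centroid = coords[nearest].mean(axis=0)
        v = coords[i] - centroid
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(f"degenerate solvent vector for residue {key}")
        vectors[key] = SolventVector(residue=key, direction=v / norm)
    return vectors


def compute_solvent_vector(
    residue: ResidueKey,
    surface: SurfaceSet,
    centers: Mapping[ResidueKey, np.ndarray],
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> SolventVector:
    """Solvent vector for one residue (see :func:`compute_solvent_vectors`)."""
    return compute_solvent_vectors(surface, centers, k_neighbors)[residue]


def generate_patches_vector(
    surface: SurfaceSet,
    centers: Mapping[ResidueKey, np.ndarray],
    radius: float,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> list[SurfacePatch]:
    """Method 3: distance cutoff plus solvent-vector angle constraint.

    A residue joins the patch only if the angle between its solvent vector and
    the central residue's is below ``angle_cutoff`` degrees (default 110°),
    preventing patches from wrapping to the opposite face of the molecule.
    The central residue is always a member.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    vectors = compute_solvent_vectors(surface, centers, k_neighbors)
    keys, coords = _surface_arrays(surface.members, centers)
    dirs = np.array([vectors[k].direction for k in keys])
    d = cdist(coords, coords)
    cos_cut = math.cos(math.radians(angle_cutoff))
    cosines = dirs @ dirs.T  # unit vectors: dot product = cos(angle)
    patches = []
    for i, key in enumerate(keys):
        ok = (d[i] <= radius) & (cosines[i] > cos_cut)
        ok[i] = True
        members = frozenset(keys[j] for j in np.nonzero(ok)[0])
        patches.append(SurfacePatch(center=key, members=members))
    return patches


def score_residue_set(
    members: Iterable[ResidueKey],
    profile: EntropyProfile,
    centers: Mapping[ResidueKey, np.ndarray],
    criterion: str = "mean",
    center: ResidueKey | None = None,
) -> SurfacePatch:
    """Score one residue set: select its conserved residues (relative to the
    set's own entropy mean) and compute ρ; residues with undefined entropy are
    dropped from scoring."""
    members = frozenset(members)
    scored = sorted(profile.defined_over(members))
    if len(scored) < 2:
        return SurfacePatch(center=center, members=members, rho=None,
                            n_scored=len(scored), n_conserved=0)
    conserved = select_conserved(profile, scored, criterion).members
    if len(conserved) < 2:
        return SurfacePatch(center=center, members=members, rho=None,
                            n_scored=len(scored), n_conserved=len(conserved))
    whole = PointSet.from_centers(centers, scored)
    result = clustering_ratio(whole.subset(conserved), whole)
    return SurfacePatch(center=center, members=members, rho=result.rho,
                        n_scored=len(scored), n_conserved=len(conserved))


def score_patches(
    patches: Sequence[SurfacePatch],
    profile: EntropyProfile,
    centers: Mapping[ResidueKey, np.ndarray],
    criterion: str = "mean",
) -> list[SurfacePatch]:
    """Score every patch (see :func:`score_residue_set`)."""
    return [
        score_residue_set(p.members, profile, centers, criterion, center=p.center)
        for p in patches
    ]


def patch_overlap_percent(patch: SurfacePatch | Iterable[ResidueKey],
                          interface: Iterable[ResidueKey]) -> float:
    """Percentage of true-interface residues contained in the patch:
    100 · |patch ∩ interface| / |interface|."""
    members = patch.members if isinstance(patch, SurfacePatch) else frozenset(patch)
    interface = frozenset(interface)
    if not interface:
        raise ValueError("interface residue set is empty")
    return 100.0 * len(members & interface) / len(interface)


@dataclass
class PatchRanking:
    """All surface patches sorted by descending ρ with the true interface ranked."""

    patches: list[SurfacePatch]
    interface_rank: int
    decile: int
    rho_interface: float | None
    z_score: float
    best_overlap_percent: float
    n_ranked: int
    interface_too_few: bool = False


def rank_interface(
    patches: Sequence[SurfacePatch],
    interface_patch: SurfacePatch,
) -> PatchRanking:
    """Rank the true interface among the surface patches by descending ρ.

    The rank is 1 + the number of comparison patches with strictly greater ρ;
    marker-valued (unscorable) patches rank below every numeric ρ.  The decile
    is computed over patches plus the interface; Z uses the mean and SD of the
    numeric comparison-patch ρ values.
    """
    if not patches:
        raise ValueError("at least one comparison patch is required")
    numeric = [p.rho for p in patches if p.rho is not None]
    total = len(patches) + 1
    ordered = sorted(
        patches, key=lambda p: (p.rho is None, -(p.rho if p.rho is not None else 0.0))
    )
    overlaps = [patch_overlap_percent(p, interface_patch.members) for p in patches]
    best_overlap = max(overlaps) if overlaps else 0.0

    if interface_patch.rho is None:
        return PatchRanking(
            patches=ordered,
            interface_rank=total,
            decile=10,
            rho_interface=None,
            z_score=float("nan"),
            best_overlap_percent=best_overlap,
            n_ranked=total,
            interface_too_few=True,
        )
    rho_int = interface_patch.rho
    rank = 1 + sum(1 for r in numeric if r > rho_int)
    decile = math.ceil(10 * rank / total)
    if numeric:
        mean = float(np.mean(numeric))
        sd = float(np.std(numeric, ddof=0))
        z = (rho_int - mean) / sd if sd > 0 else float("nan")
    else:
        z = float("nan")
    return PatchRanking(
        patches=ordered,
        interface_rank=rank,
        decile=decile,
        rho_interface=rho_int,
        z_score=z,
        best_overlap_percent=best_overlap,
        n_ranked=total,
    )
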