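"""Synthetic fixtures: toy complexes, alignments and ΔΔG annotations with known truth.

Pseudo-structures use two beads per residue (a backbone bead ``CA`` and a
side-chain bead ``CB``, both carbon), enough for centers of mass, solvent
accessibility and pairwise distances without rotamer realism.  Two geometries:

- ``two-slab``: each chain is a planar lattice of residues (6.5 Å spacing);
  a designed rectangular block on each chain bulges toward the partner so
  that exactly the block residues come into contact (4.6 Å bead gap, well
  inside the 6.2 Å occlusion range of carbon + a 1.4 Å probe) while all
  other cross-chain bead pairs stay ≥ 14 Å apart.  Interface recovery by
  buried-area analysis is therefore exact by construction.
- ``sphere-contact``: each chain is a Fibonacci sphere shell; the two shells
  touch pole-to-pole and a designated polar cap of ``interface_size``
  residues per chain plays the role of the interface.

Conserved residues are planted inside the interface either as one or more
tight blobs (``clustered``; ``cluster_count`` blobs placed at well-separated
corners of the block) or uniformly at random over the interface
(``scattered``).  Alignments give planted-conserved columns zero class
entropy and all other columns an independent class-entropy target of
``noise_entropy`` nats.  All generators are deterministic per (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from scipy.optimize import brentq

from .structure import (
    ONE_TO_THREE,
    ResidueKey,
    StructureModel,
    compute_sasa,
)
from .conservation import Alignment, DEFAULT_CLASS_SCHEME, GAP_CHARS
from .enrichment import HotspotAnnotation

SPACING = 6.5          # Å lattice constant between residue centers
CB_OFFSET = 2.5        # Å side-chain bead offset from the backbone bead
CONTACT_GAP = 4.6      # Å bead gap across the designed contact
SLAB_GAP = 24.0        # Å bead gap everywhere else (far outside occlusion range)
JITTER_SD = 0.25       # Å in-plane coordinate jitter
AMINO_3 = sorted(ONE_TO_THREE.values())

_CLASS_MEMBERS: dict[int, list[str]] = {}
for _aa, _k in DEFAULT_CLASS_SCHEME.items():
    _CLASS_MEMBERS.setdefault(_k, []).append(_aa)
for _k in _CLASS_MEMBERS:
    _CLASS_MEMBERS[_k].sort()


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass
class FixtureSpec:
    """Parameters of a synthetic complex + alignment fixture."""

    n_residues_per_chain: int = 96
    interface_size: int = 16
    conserved_fraction: float = 0.25
    placement: str = "clustered"          # 'clustered' | 'scattered'
    cluster_count: int = 1
    geometry: str = "two-slab"            # 'two-slab' | 'sphere-contact'
    msa_depth: int = 60
    noise_entropy: float = math.log(2.0)  # nats
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.conserved_fraction < 1:
            raise FixtureError("conserved_fraction must be in (0, 1)")
        if self.msa_depth < 2:
            raise FixtureError("msa_depth must be at least 2")
        if self.placement not in ("clustered", "scattered"):
            raise FixtureError(f"unknown placement {self.placement!r}")
        if self.geometry not in ("two-slab", "sphere-contact"):
            raise FixtureError(f"unknown geometry {self.geometry!r}")
        if self.interface_size > self.n_residues_per_chain:
            raise FixtureError("interface_size exceeds chain size")
        if self.cluster_count < 1 or self.cluster_count > 4:
            raise FixtureError("cluster_count must be between 1 and 4")
        if self.noise_entropy < 0 or self.noise_entropy > math.log(7) + 1e-12:
            raise FixtureError("noise_entropy must lie in [0, ln 7]")


@dataclass
class FixtureTruth:
    """Ground truth recorded by the generators (never re-derived by tests)."""

    true_interface: dict[str, set[ResidueKey]]
    true_conserved: set[ResidueKey]
    true_subclusters: list[frozenset[ResidueKey]]
    solvent_directions: dict[ResidueKey, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        def keylist(keys):
            return sorted([k.chain_id, k.residue_number, k.insertion_code] for k in keys)

        payload = {
            "true_interface": {c: keylist(s) for c, s in self.true_interface.items()},
            "true_conserved": keylist(self.true_conserved),
            "true_subclusters": [keylist(c) for c in self.true_subclusters],
            "solvent_directions": {
                f"{k.chain_id}:{k.residue_number}:{k.insertion_code}": [float(x) for x in v]
                for k, v in sorted(self.solvent_directions.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _factor_grid(n: int) -> tuple[int, int]:
    """Most-square (nx, ny) factorisation with nx >= ny."""
    ny = int(math.sqrt(n))
    while ny > 1 and n % ny:
        ny -= 1
    return n // ny, ny


def _build_model(records: Sequence[tuple[str, int, str, str, np.ndarray]]) -> StructureModel:
    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r[4] for r in records], dtype=float)
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3] for r in records])
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    arr.ins_code = np.array([""] * n)
    arr.set_annotation("occupancy", np.ones(n))
    return StructureModel(arr)


#: public name for ad-hoc toy models in user code and tests
def build_bead_model(records: Sequence[tuple[str, int, str, str, np.ndarray]]) -> StructureModel:
    """Build a :class:`StructureModel` from (chain, res_id, res_name, atom_name, xyz)
    carbon-bead records (the representation all fixture geometries use)."""
    return _build_model(records)


def _blob_targets(bx: int, by: int, k: int) -> list[tuple[float, float]]:
    """Grid-unit anchor points for k well-separated conserved blobs in a bx×by block."""
    corners = [(0.0, 0.0), (bx - 1.0, by - 1.0), (bx - 1.0, 0.0), (0.0, by - 1.0)]
    if k == 1:
        return [((bx - 1) / 2.0, (by - 1) / 2.0)]
    return corners[:k]


def _pick_blobs(
    block: list[tuple[int, int]], m: int, k: int, bx: int, by: int
) -> list[list[tuple[int, int]]]:
    sizes = [m // k + (1 if i < m % k else 0) for i in range(k)]
    taken: set[tuple[int, int]] = set()
    blobs = []
    for target, size in zip(_blob_targets(bx, by, k), sizes):
        free = [c for c in block if c not in taken]
        free.sort(key=lambda c: ((c[0] - target[0]) ** 2 + (c[1] - target[1]) ** 2, c))
        blob = free[:size]
        taken.update(blob)
        blobs.append(blob)
    return blobs


def _random_names(rng: np.random.Generator, n: int) -> list[str]:
    return [AMINO_3[i] for i in rng.integers(0, len(AMINO_3), size=n)]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_complex(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    """Build a deterministic toy two-chain complex with recorded ground truth."""
    rng = np.random.default_rng([spec.seed, 11])
    if spec.geometry == "two-slab":
        return _make_two_slab(spec, rng)
    return _make_sphere_contact(spec, rng)


def _make_two_slab(spec: FixtureSpec, rng: np.random.Generator):
    n = spec.n_residues_per_chain
    nx, ny = _factor_grid(n)
    bx, by = _factor_grid(spec.interface_size)
    if bx > nx or by > ny:
        raise FixtureError(
            f"interface block {bx}x{by} does not fit the {nx}x{ny} chain lattice"
        )
    x0, y0 = (nx - bx) // 2, (ny - by) // 2
    block = [(ix, iy) for iy in range(by) for ix in range(bx)]
    m_cons = max(int(round(spec.conserved_fraction * spec.interface_size)), spec.cluster_count)

    if spec.placement == "clustered":
        blobs = _pick_blobs(block, m_cons, spec.cluster_count, bx, by)
    else:
        idx = rng.choice(len(block), size=m_cons, replace=False)
        blobs = [[block[i] for i in idx]]

    bulge = (SLAB_GAP - CONTACT_GAP) / 2.0
    names = {"A": _random_names(rng, n), "B": _random_names(rng, n)}
    records = []
    interface: dict[str, set[ResidueKey]] = {"A": set(), "B": set()}
    block_set = set(block)
    for chain, sign, z_base in (("A", -1.0, 0.0), ("B", +1.0, SLAB_GAP)):
        for iy in range(ny):
            for ix in range(nx):
                res_id = iy * nx + ix + 1
                in_block = (ix - x0, iy - y0) in block_set
                if in_block:
                    interface[chain].add(ResidueKey(chain, res_id, ""))
                x = (ix - (nx - 1) / 2.0) * SPACING + rng.normal(0.0, JITTER_SD)
                y = (iy - (ny - 1) / 2.0) * SPACING + rng.normal(0.0, JITTER_SD)
                z = z_base - sign * (bulge if in_block else 0.0)
                name = names[chain][res_id - 1]
                records.append((chain, res_id, name, "CA", np.array([x, y, z])))
                records.append((chain, res_id, name, "CB", np.array([x, y, z + sign * CB_OFFSET])))

    def key_of(cell):
        ix, iy = cell
        return ResidueKey("A", (iy + y0) * nx + (ix + x0) + 1, "")

    subclusters = [frozenset(key_of(c) for c in blob) for blob in blobs]
    conserved = set().union(*subclusters)
    truth = FixtureTruth(
        true_interface=interface,
        true_conserved=conserved,
        true_subclusters=subclusters,
        solvent_directions={},
    )
    return _build_model(records), truth


def _make_sphere_contact(spec: FixtureSpec, rng: np.random.Generator):
    n = spec.n_residues_per_chain
    radius = SPACING * math.sqrt(n / (4.0 * math.pi))
    units = _fibonacci_sphere(n)
    center_b = np.array([0.0, 0.0, 2.0 * radius + CONTACT_GAP])
    names = {"A": _random_names(rng, n), "B": _random_names(rng, n)}

    # designated contact caps: residues nearest the facing poles
    order_a = np.argsort(-units[:, 2], kind="stable")[: spec.interface_size]
    order_b = np.argsort(units[:, 2], kind="stable")[: spec.interface_size]
    interface = {
        "A": {ResidueKey("A", int(i) + 1, "") for i in order_a},
        "B": {ResidueKey("B", int(i) + 1, "") for i in order_b},
    }
    m_cons = max(int(round(spec.conserved_fraction * spec.interface_size)), 1)
    cap_sorted = sorted(order_a, key=lambda i: -units[i, 2])
    if spec.placement == "clustered":
        chosen = cap_sorted[:m_cons]
    else:
        chosen = rng.choice(np.array(sorted(order_a)), size=m_cons, replace=False)
    conserved = {ResidueKey("A", int(i) + 1, "") for i in chosen}

    records = []
    directions: dict[ResidueKey, np.ndarray] = {}
    for chain, origin in (("A", np.zeros(3)), ("B", center_b)):
        for i in range(n):
            u = units[i]
            jit = rng.normal(0.0, JITTER_SD, size=3)
            ca = origin + radius * u + jit
            cb = origin + (radius - CB_OFFSET) * u + jit
            name = names[chain][i]
            records.append((chain, i + 1, name, "CA", ca))
            records.append((chain, i + 1, name, "CB", cb))
            directions[ResidueKey(chain, i + 1, "")] = u.copy()

    truth = FixtureTruth(
        true_interface=interface,
        true_conserved=conserved,
        true_subclusters=[frozenset(conserved)],
        solvent_directions=directions,
    )
    return _build_model(records), truth


def make_thick_slab(
    nx: int = 8, ny: int = 8, thickness: float = 8.0, seed: int = 0
) -> tuple[StructureModel, dict[ResidueKey, str]]:
    """Single-chain, two-layer slab; returns the model and a top/bottom label per residue.

    Used to exercise the solvent-vector angle constraint: the two faces have
    anti-parallel solvent vectors, so one patch must never span both.
    """
    rng = np.random.default_rng([seed, 13])
    names = _random_names(rng, 2 * nx * ny)
    records = []
    layers: dict[ResidueKey, str] = {}
    res_id = 0
    for layer, z, sign in (("bottom", 0.0, -1.0), ("top", thickness, +1.0)):
        for iy in range(ny):
            for ix in range(nx):
                res_id += 1
                x = (ix - (nx - 1) / 2.0) * SPACING + rng.normal(0.0, JITTER_SD)
                y = (iy - (ny - 1) / 2.0) * SPACING + rng.normal(0.0, JITTER_SD)
                name = names[res_id - 1]
                records.append(("A", res_id, name, "CA", np.array([x, y, z])))
                records.append(("A", res_id, name, "CB", np.array([x, y, z + sign * CB_OFFSET])))
                layers[ResidueKey("A", res_id, "")] = layer
    return _build_model(records), layers


def _entropy_target_distribution(h: float, query_class: int, rng: np.random.Generator):
    """Class labels and probabilities whose entropy equals h nats.

    Uses the query's class plus (k-1) alternatives, k minimal with ln k >= h;
    the query class gets probability p solved from
    -p ln p - (1-p) ln((1-p)/(k-1)) = h.
    """
    if h < 0 or h > math.log(7) + 1e-12:
        raise FixtureError("noise_entropy must lie in [0, ln 7]")
    k = 1
    while math.log(max(k, 1)) < h - 1e-12:
        k += 1
    k = max(k, 2) if h > 0 else 1
    others = [c for c in range(1, 8) if c != query_class]
    classes = [query_class] + list(rng.choice(others, size=k - 1, replace=False)) if k > 1 else [query_class]
    if k == 1:
        return classes, np.array([1.0])

    def entropy_gap(p):
        q = (1.0 - p) / (k - 1)
        val = -p * math.log(p)
        if q > 0:
            val -= (k - 1) * q * math.log(q)
        return val - h

    lo, hi = 1.0 / k, 1.0 - 1e-12
    if entropy_gap(hi) > 0:  # h ~ 0: p -> 1
        p = hi
    else:
        p = brentq(entropy_gap, lo, hi)
    probs = np.full(k, (1.0 - p) / (k - 1))
    probs[0] = p
    return classes, probs


def _letter_from_class(k: int, rng: np.random.Generator) -> str:
    members = _CLASS_MEMBERS[k]
    return members[int(rng.integers(0, len(members)))]


def make_alignment(
    spec: FixtureSpec,
    truth: FixtureTruth,
    chain: StructureModel,
    chain_id: str = "A",
) -> Alignment:
    """Alignment whose query row is the chain sequence: planted-conserved columns
    vary only within one class (entropy 0), all others hit ``noise_entropy``."""
    rng = np.random.default_rng([spec.seed, 17])
    keys = chain.residue_keys([chain_id])
    query = chain.sequence(chain_id)
    depth = spec.msa_depth
    columns: list[list[str]] = []
    for key, q in zip(keys, query):
        q_class = DEFAULT_CLASS_SCHEME[q]
        col = [q]
        if key in truth.true_conserved:
            col.extend(_letter_from_class(q_class, rng) for _ in range(depth - 1))
        else:
            classes, probs = _entropy_target_distribution(spec.noise_entropy, q_class, rng)
            draws = rng.choice(len(classes), size=depth - 1, p=probs)
            col.extend(_letter_from_class(classes[int(d)], rng) for d in draws)
        columns.append(col)
    rows = ["".join(col[r] for col in columns) for r in range(depth)]
    ids = ["query"] + [f"homolog{r}" for r in range(1, depth)]
    return Alignment(sequences=rows, ids=ids, query_index=0)


def make_hotspot_annotations(
    truth: FixtureTruth,
    inside_fraction: float,
    n_hot: int,
    seed: int,
    chain_id: str = "A",
    hot_ddg_range: tuple[float, float] = (2.0, 4.0),
) -> list[HotspotAnnotation]:
    """ΔΔG annotations with an exactly planted in-cluster fraction of hot residues.

    ``round(inside_fraction * n_hot)`` hot residues (ΔΔG ≥ 2) are placed inside
    the planted conserved clusters, the rest on other interface residues; all
    remaining interface residues get ΔΔG in [0, 1).
    """
    if not 0 <= inside_fraction <= 1:
        raise FixtureError("inside_fraction must lie in [0, 1]")
    interface = truth.true_interface[chain_id]
    if n_hot > len(interface):
        raise FixtureError("n_hot exceeds the interface size")
    rng = np.random.default_rng([seed, 23])
    inside_pool = sorted(truth.true_conserved & interface)
    outside_pool = sorted(interface - truth.true_conserved)
    n_in = int(round(inside_fraction * n_hot))
    n_out = n_hot - n_in
    if n_in > len(inside_pool) or n_out > len(outside_pool):
        raise FixtureError(
            f"cannot plant {n_in} in-cluster and {n_out} out-of-cluster hot residues"
        )
    hot = [inside_pool[i] for i in rng.choice(len(inside_pool), size=n_in, replace=False)]
    hot += [outside_pool[i] for i in rng.choice(len(outside_pool), size=n_out, replace=False)]
    lo, hi = hot_ddg_range
    annotations = [
        HotspotAnnotation(residue=k, ddg=float(rng.uniform(lo, hi))) for k in hot
    ]
    hot_set = set(hot)
    for k in sorted(interface - hot_set):
        annotations.append(HotspotAnnotation(residue=k, ddg=float(rng.uniform(0.0, 1.0))))
    return sorted(annotations)


@lru_cache(maxsize=4)
def fixture_reference_asa(probe_radius: float = 1.4, n_points: int = 960) -> tuple:
    """Reference maximal accessibility for the toy two-bead residues.

    Computed as the SASA of the central residue of an isolated, extended
    three-residue strip (the same convention as extended-tripeptide reference
    tables for real amino acids).  Returned as a hashable tuple of
    (residue_name, area) pairs; use :func:`fixture_reference_table`.
    """
    records = []
    for i, x in enumerate((-SPACING, 0.0, SPACING)):
        records.append(("A", i + 1, "ALA", "CA", np.array([x, 0.0, 0.0])))
        records.append(("A", i + 1, "ALA", "CB", np.array([x, 0.0, -CB_OFFSET])))
    model = _build_model(records)
    areas = compute_sasa(model, probe_radius=probe_radius, n_points=n_points)
    central = model.residue_atom_indices(ResidueKey("A", 2, ""))
    ref = float(areas[central].sum())
    return tuple((name, ref) for name in AMINO_3)


def fixture_reference_table(probe_radius: float = 1.4, n_points: int = 960) -> dict[str, float]:
    """Reference accessibility table (3-letter name → Å²) for fixture structures."""
    return dict(fixture_reference_asa(probe_radius, n_points))
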