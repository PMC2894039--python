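"""End-to-end orchestration: per-interface clustering reports and binding-site prediction.

Two entry points mirror the two analyses:

- :func:`analyze_complex` — given a complex and an alignment for the analyzed
  chain: interface detection (ΔASA), entropy mapping, conserved-residue
  selection, clustering ratio ρ with its random-subset significance test,
  average-linkage sub-clusters, amino-acid enrichment and (optionally)
  hot-spot localization, all gathered into one :class:`InterfaceReport`.
- :func:`predict_binding_site` — given a single chain and its alignment:
  surface detection, patch generation (Method 1, 2 or 3), per-patch ρ and,
  in evaluation mode, the rank/decile/Z of the true interface.

File-based wrappers (:func:`run_interface_analysis`,
:func:`run_binding_site_prediction`) read PDB/FASTA/TSV inputs and write
deterministic JSON/TSV reports stamped with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__ as _version
from .structure import (
    InterfaceRecord,
    ResidueKey,
    StructureModel,
    identify_interface,
    interface_report_frame,
    read_structure,
    surface_residues,
)
from .conservation import (
    Alignment,
    ConservedSet,
    EntropyProfile,
    entropy_profile,
    map_query_to_structure,
    profile_report_frame,
    read_alignment,
    read_background,
    select_conserved,
)
from .cluster import (
    LINKAGE_THRESHOLDS,
    ClusteringResult,
    DEFAULT_SEED,
    PointSet,
    RandomSubsetTest,
    SubclusterPartition,
    average_linkage_subclusters,
    clustering_ratio,
    random_subset_test,
    subcluster_report_frame,
)
from .patches import (
    PATCH_RADII,
    PatchRanking,
    SurfacePatch,
    adaptive_patch_radius,
    generate_patches_fixed,
    generate_patches_vector,
    interface_atom_coords,
    rank_interface,
    score_patches,
    score_residue_set,
)
from .enrichment import (
    EnrichmentTable,
    HotspotAnnotation,
    enrichment_report_frame,
    hotspot_localization,
    read_ddg_table,
    residue_enrichment,
)


@dataclass
class RunConfig:
    """Configuration of one analysis run; every field except the inputs has a default."""

    pdb_path: str = ""
    msa_path: str = ""
    chains_a: tuple[str, ...] = ()
    chains_b: tuple[str, ...] = ()
    flavor: str = "complex"          # 'complex' | 'homodimer'
    criterion: str = "mean"          # 'mean' | 'mean-sd' | 'zero'
    entropy_kind: str = "plain"      # 'plain' | 'relative'
    background_path: str = ""
    ddg_path: str = ""
    patch_method: int = 1
    radius: float | None = None
    angle_cutoff: float = 110.0
    burial_threshold: float = 0.1
    surface_threshold: float = 0.05
    linkage_threshold: float | None = None
    n_random: int = 1000
    probe_radius: float = 1.4
    n_points: int = 960
    seed: int = DEFAULT_SEED
    out_dir: str = "consite_out"
    fmt: str = "json"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class InterfaceReport:
    """All per-interface results derived from one conserved set."""

    interface: InterfaceRecord
    analyzed_chain: str
    analyzed_residues: list[ResidueKey]
    profile: EntropyProfile
    conserved: ConservedSet
    clustering: ClusteringResult
    random_test: RandomSubsetTest
    subclusters: SubclusterPartition
    enrichment: EnrichmentTable
    hotspots: dict[float, tuple] | None = None
    criterion: str = "mean"
    seed: int = DEFAULT_SEED


def _key_str(key: ResidueKey) -> str:
    return f"{key.chain_id}:{key.residue_number}:{key.insertion_code}"


def analyze_complex(
    structure: StructureModel,
    alignment: Alignment,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    *,
    analyzed_chain: str | None = None,
    flavor: str = "complex",
    criterion: str = "mean",
    entropy_kind: str = "plain",
    background: Mapping[int, float] | None = None,
    annotations: Sequence[HotspotAnnotation] | None = None,
    burial_threshold: float = 0.1,
    linkage_threshold: float | None = None,
    n_random: int = 1000,
    probe_radius: float = 1.4,
    n_points: int = 960,
    seed: int = DEFAULT_SEED,
    interface: InterfaceRecord | None = None,
) -> InterfaceReport:
    """Full per-interface conservation-clustering analysis (one analyzed chain).

    The conserved subset, its clustering ratio ρ, the random-subset test, the
    sub-cluster partition and the enrichment table are all computed over the
    interface residues of ``analyzed_chain`` (default: the first chain of
    ``chains_a``), using the entropy mean/SD of that same residue set.
    A precomputed ``interface`` record may be passed to skip the ΔASA step.
    """
    if flavor not in LINKAGE_THRESHOLDS:
        raise ValueError(f"unknown flavor {flavor!r}")
    if interface is None:
        interface = identify_interface(
            structure, chains_a, chains_b,
            burial_threshold=burial_threshold,
            probe_radius=probe_radius, n_points=n_points,
        )
    chain = analyzed_chain or tuple(chains_a)[0]
    chain_model = structure.subset([chain])
    column_map = map_query_to_structure(alignment, chain_model, chain)
    profile = entropy_profile(alignment, column_map, kind=entropy_kind, background=background)

    over = sorted(k for k in interface.partner_a
                  if k.chain_id == chain and k in profile.values)
    if len(over) < 2:
        raise ValueError(
            f"only {len(over)} interface residue(s) with defined entropy on chain {chain}"
        )
    conserved = select_conserved(profile, over, criterion)
    centers = structure.residue_centers(over)
    whole = PointSet.from_centers(centers)
    subset = whole.subset(conserved.members)
    clustering = clustering_ratio(subset, whole)
    random_test = random_subset_test(
        whole, len(conserved.members), clustering.m_s_subset,
        n_trials=n_random, seed=seed,
    )
    threshold = linkage_threshold if linkage_threshold is not None else LINKAGE_THRESHOLDS[flavor]
    subclusters = average_linkage_subclusters(subset, threshold)
    enrichment = residue_enrichment(conserved.members, over, structure.residue_names(over))
    hotspots = None
    if annotations is not None:
        hotspots = hotspot_localization(subclusters, annotations)
    return InterfaceReport(
        interface=interface,
        analyzed_chain=chain,
        analyzed_residues=over,
        profile=profile,
        conserved=conserved,
        clustering=clustering,
        random_test=random_test,
        subclusters=subclusters,
        enrichment=enrichment,
        hotspots={c: tuple(r) for c, r in hotspots.items()} if hotspots else None,
        criterion=conserved.criterion,
        seed=seed,
    )


def predict_binding_site(
    structure: StructureModel,
    alignment: Alignment,
    chain_id: str | None = None,
    *,
    method: int = 1,
    flavor: str = "complex",
    radius: float | None = None,
    angle_cutoff: float = 110.0,
    k_neighbors: int = 10,
    criterion: str = "mean",
    entropy_kind: str = "plain",
    background: Mapping[int, float] | None = None,
    surface_threshold: float = 0.05,
    reference_table: Mapping[str, float] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    true_interface: Iterable[ResidueKey] | None = None,
) -> PatchRanking | list[SurfacePatch]:
    """Rank surface patches by conserved-residue clustering.

    With ``true_interface`` (evaluation mode) returns a :class:`PatchRanking`
    with the interface's rank, decile, Z-score and best patch overlap; without
    it returns the scored patches sorted by descending ρ (prediction mode).
    Methods 2 and 3 derive their radius from the true interface; in prediction
    mode pass ``radius`` explicitly for those methods.
    """
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    if chain_id is None:
        ids = structure.chain_ids
        if len(ids) != 1:
            raise ValueError(f"structure has chains {ids}; pass chain_id")
        chain_id = ids[0]
    chain_model = structure.subset([chain_id])
    surface = surface_residues(
        chain_model, rel_threshold=surface_threshold,
        reference_table=reference_table,
        probe_radius=probe_radius, n_points=n_points,
    )
    centers = chain_model.residue_centers()
    column_map = map_query_to_structure(alignment, chain_model, chain_id)
    profile = entropy_profile(alignment, column_map, kind=entropy_kind, background=background)

    if radius is None:
        if method == 1:
            radius = PATCH_RADII[flavor]
        else:
            if true_interface is None:
                raise ValueError(
                    f"method {method} derives its radius from the true interface; "
                    "pass radius explicitly in prediction mode"
                )
            radius = adaptive_patch_radius(
                interface_atom_coords(chain_model, true_interface)
            )
    if method == 3:
        patches = generate_patches_vector(
            surface, centers, radius, angle_cutoff=angle_cutoff, k_neighbors=k_neighbors
        )
    else:
        patches = generate_patches_fixed(surface, centers, radius)
    scored = score_patches(patches, profile, centers, criterion)

    if true_interface is None:
        return sorted(
            scored, key=lambda p: (p.rho is None, -(p.rho if p.rho is not None else 0.0))
        )
    interface_patch = score_residue_set(
        set(true_interface), profile, centers, criterion
    )
    return rank_interface(scored, interface_patch)


# ---------------------------------------------------------------------------
# serialization

def _round(x, nd=10):
    if x is None:
        return None
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return str(x)
    return round(float(x), nd)


def interface_report_dict(report: InterfaceReport, config: RunConfig | None = None) -> dict:
    """JSON-ready dict of an interface report (deterministic: sorted, no timestamps)."""
    rec = report.interface
    payload = {
        "version": _version,
        "analyzed_chain": report.analyzed_chain,
        "criterion": report.criterion,
        "seed": report.seed,
        "interface": {
            "n_partner_a": len(rec.partner_a),
            "n_partner_b": len(rec.partner_b),
            "buried_area_a": _round(rec.buried_area("a")),
            "buried_area_b": _round(rec.buried_area("b")),
            "chain_partition": [list(g) for g in rec.chain_partition],
        },
        "entropy": {
            "kind": report.profile.kind,
            "mean_interface": _round(report.conserved.mean_entropy),
            "sd_interface": _round(report.conserved.sd_entropy),
            "n_analyzed": len(report.analyzed_residues),
        },
        "conserved": {
            "n": len(report.conserved.members),
            "members": sorted(_key_str(k) for k in report.conserved.members),
        },
        "clustering": {
            "m_s_cons": _round(report.clustering.m_s_subset),
            "m_s_int": _round(report.clustering.m_s_whole),
            "rho": _round(report.clustering.rho),
        },
        "random_test": {
            "n_trials": report.random_test.n_trials,
            "mean_random": _round(report.random_test.mean_random),
            "sd_random": _round(report.random_test.sd_random),
            "p_empirical": _round(report.random_test.p_empirical),
            "seed": report.random_test.seed,
        },
        "subclusters": {
            "threshold": report.subclusters.threshold,
            "n_clusters": report.subclusters.n_clusters,
            "sizes": report.subclusters.sizes(),
            "clusters": sorted(sorted(_key_str(k) for k in c) for c in report.subclusters.clusters),
        },
        "enrichment": {
            aa: _round(v) for aa, v in sorted(report.enrichment.e_x.items()) if v is not None
        },
    }
    if report.hotspots is not None:
        payload["hotspots"] = {
            str(c): {"n_hot": r[1], "n_in_clusters": r[2], "fraction": _round(r[3])}
            for c, r in sorted(report.hotspots.items())
        }
    if config is not None:
        payload["config"] = asdict(config)
        payload["config_hash"] = config.config_hash()
    return payload


def ranking_report_dict(ranking: PatchRanking, config: RunConfig | None = None) -> dict:
    payload = {
        "version": _version,
        "n_ranked": ranking.n_ranked,
        "interface_rank": ranking.interface_rank,
        "decile": ranking.decile,
        "rho_interface": _round(ranking.rho_interface),
        "z_score": _round(ranking.z_score),
        "best_overlap_percent": _round(ranking.best_overlap_percent),
        "interface_too_few": ranking.interface_too_few,
        "patches": [
            {
                "center": _key_str(p.center) if p.center else None,
                "size": len(p.members),
                "n_conserved": p.n_conserved,
                "rho": _round(p.rho),
            }
            for p in ranking.patches
        ],
    }
    if config is not None:
        payload["config"] = asdict(config)
        payload["config_hash"] = config.config_hash()
    return payload


def report_json(payload: dict) -> str:
    return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# file-based runs

def run_interface_analysis(config: RunConfig) -> InterfaceReport:
    """File-based wrapper: read inputs, analyze, write reports under out_dir."""
    structure = read_structure(config.pdb_path)
    alignment = read_alignment(config.msa_path)
    background = read_background(config.background_path) if config.background_path else None
    annotations = None
    if config.ddg_path:
        annotations = read_ddg_table(config.ddg_path, structure)
    report = analyze_complex(
        structure, alignment, config.chains_a, config.chains_b,
        flavor=config.flavor, criterion=config.criterion,
        entropy_kind=config.entropy_kind, background=background,
        annotations=annotations,
        burial_threshold=config.burial_threshold,
        linkage_threshold=config.linkage_threshold,
        n_random=config.n_random,
        probe_radius=config.probe_radius, n_points=config.n_points,
        seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(interface_report_dict(report, config)) + "\n")
    interface_report_frame(report.interface, structure).to_csv(
        out / "interface.tsv", sep="\t", index=False
    )
    profile_report_frame(report.profile, structure, report.analyzed_residues).to_csv(
        out / "entropy.tsv", sep="\t", index=False
    )
    centers = structure.residue_centers(report.conserved.members)
    subcluster_report_frame(report.subclusters, centers).to_csv(
        out / "subclusters.tsv", sep="\t", index=False
    )
    enrichment_report_frame(report.enrichment).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    return report


def run_binding_site_prediction(config: RunConfig,
                                true_interface: Iterable[ResidueKey] | None = None):
    """File-based wrapper around :func:`predict_binding_site`."""
    from .structure import surface_report_frame

    structure = read_structure(config.pdb_path)
    alignment = read_alignment(config.msa_path)
    background = read_background(config.background_path) if config.background_path else None
    chain = config.chains_a[0] if config.chains_a else None
    result = predict_binding_site(
        structure, alignment, chain,
        method=config.patch_method, flavor=config.flavor,
        radius=config.radius, angle_cutoff=config.angle_cutoff,
        criterion=config.criterion, entropy_kind=config.entropy_kind,
        background=background, surface_threshold=config.surface_threshold,
        probe_radius=config.probe_radius, n_points=config.n_points,
        true_interface=true_interface,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(result, PatchRanking):
        payload = ranking_report_dict(result, config)
    else:
        payload = {
            "version": _version,
            "patches": [
                {
                    "center": _key_str(p.center) if p.center else None,
                    "size": len(p.members),
                    "n_conserved": p.n_conserved,
                    "rho": _round(p.rho),
                }
                for p in result
            ],
            "config": asdict(config),
            "config_hash": config.config_hash(),
        }
    (out / "ranking.json").write_text(report_json(payload) + "\n")
    chain_model = structure.subset([chain]) if chain else structure
    surface = surface_residues(
        chain_model, rel_threshold=config.surface_threshold,
        probe_radius=config.probe_radius, n_points=config.n_points,
    )
    surface_report_frame(surface, structure).to_csv(
        out / "surface.tsv", sep="\t", index=False
    )
    return result
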