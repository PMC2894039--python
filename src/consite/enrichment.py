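"""Amino-acid enrichment in conserved subsets and hot-spot localization.

The enrichment of amino acid X is the ratio of its frequency among conserved
interface residues to its frequency in the whole interface,
E_X = f_cons(X) / f_int(X); E_X > 1 means X is over-represented in the
conserved subset.

Hot spots are interface residues whose alanine mutation changes the binding
free energy by at least a cutoff (1, 1.5 or 2 kcal/mol); the fraction of them
that fall inside the conserved spatial sub-clusters measures how well the
clusters localize energetically important residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .structure import ResidueKey, StructureModel, THREE_TO_ONE
from .cluster import SubclusterPartition

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_DDG_CUTOFFS = (1.0, 1.5, 2.0)


@dataclass
class EnrichmentTable:
    """Per-amino-acid enrichment E_X with the underlying counts.

    ``e_x[X]`` is None (undefined) for amino acids absent from the interface.
    """

    e_x: dict[str, float | None]
    counts_conserved: dict[str, int]
    counts_interface: dict[str, int]


def _one_letter(name: str) -> str:
    if len(name) == 1:
        return name.upper()
    try:
        return THREE_TO_ONE[name.upper()]
    except KeyError:
        raise ValueError(f"unknown residue name {name!r}") from None


def residue_enrichment(
    conserved: Iterable[ResidueKey],
    interface: Iterable[ResidueKey],
    residue_names: Mapping[ResidueKey, str],
) -> EnrichmentTable:
    """E_X = (frequency of X among conserved) / (frequency of X in interface)."""
    conserved = set(conserved)
    interface = set(interface)
    if not interface:
        raise ValueError("interface residue set is empty")
    if not conserved <= interface:
        raise ValueError("conserved residues must be a subset of the interface")
    counts_int = {aa: 0 for aa in AMINO_ACIDS}
    counts_con = {aa: 0 for aa in AMINO_ACIDS}
    for key in interface:
        aa = _one_letter(residue_names[key])
        counts_int[aa] = counts_int.get(aa, 0) + 1
        if key in conserved:
            counts_con[aa] = counts_con.get(aa, 0) + 1
    n_int = len(interface)
    n_con = len(conserved)
    e_x: dict[str, float | None] = {}
    for aa in counts_int:
        if counts_int[aa] == 0:
            e_x[aa] = None
        elif n_con == 0:
            e_x[aa] = 0.0
        else:
            e_x[aa] = (counts_con[aa] / n_con) / (counts_int[aa] / n_int)
    return EnrichmentTable(e_x=e_x, counts_conserved=counts_con, counts_interface=counts_int)


class HotspotAnnotation(NamedTuple):
    """Experimental alanine-scanning result for one interface residue (kcal/mol)."""

    residue: ResidueKey
    ddg: float


class HotspotResult(NamedTuple):
    cutoff: float
    n_hot: int
    n_in_clusters: int
    fraction: float


def read_ddg_table(path, structure: StructureModel | None = None) -> list[HotspotAnnotation]:
    """Read a ΔΔG TSV (chain, resnum, icode, resname, ddg).

    When a structure is supplied, residue names are cross-checked against the
    coordinates to guard against numbering drift.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str}, keep_default_na=False)
    required = {"chain", "resnum", "icode", "resname", "ddg"}
    if not required <= set(df.columns):
        raise ValueError(f"ΔΔG table must have columns {sorted(required)}")
    annotations = []
    for row in df.itertuples(index=False):
        key = ResidueKey(str(row.chain), int(row.resnum), str(row.icode))
        ddg = float(row.ddg)
        if not (ddg == ddg and abs(ddg) != float("inf")):
            raise ValueError(f"non-finite ΔΔG for residue {key}")
        if structure is not None:
            observed = structure.residue_name(key)
            if observed.upper() != str(row.resname).upper():
                raise ValueError(
                    f"residue name mismatch at {key}: table says {row.resname}, "
                    f"structure says {observed}"
                )
        annotations.append(HotspotAnnotation(residue=key, ddg=ddg))
    return annotations


def write_ddg_table(annotations: Sequence[HotspotAnnotation],
                    residue_names: Mapping[ResidueKey, str], path) -> None:
    import pandas as pd

    rows = [
        {
            "chain": a.residue.chain_id,
            "resnum": a.residue.residue_number,
            "icode": a.residue.insertion_code,
            "resname": residue_names[a.residue],
            "ddg": a.ddg,
        }
        for a in sorted(annotations)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hotspot_localization(
    clusters: SubclusterPartition,
    annotations: Sequence[HotspotAnnotation],
    cutoffs: Sequence[float] = DEFAULT_DDG_CUTOFFS,
    interface: Iterable[ResidueKey] | None = None,
    include_singletons: bool = True,
) -> dict[float, HotspotResult]:
    """Per-cutoff fraction of hot residues (ΔΔG ≥ cutoff) inside conserved clusters.

    Singleton clusters count as clusters by default (``include_singletons``).
    If ``interface`` is given, annotations outside it raise an error.
    """
    if interface is not None:
        interface = set(interface)
        unknown = [a.residue for a in annotations if a.residue not in interface]
        if unknown:
            raise ValueError(f"annotations reference unknown interface residues: {unknown[:5]}")
    in_clusters = clusters.members(include_singletons=include_singletons)
    results: dict[float, HotspotResult] = {}
    for cutoff in cutoffs:
        hot = [a.residue for a in annotations if a.ddg >= cutoff]
        n_in = sum(1 for r in hot if r in in_clusters)
        fraction = n_in / len(hot) if hot else 0.0
        results[cutoff] = HotspotResult(
            cutoff=cutoff, n_hot=len(hot), n_in_clusters=n_in, fraction=fraction
        )
    return results


def enrichment_report_frame(table: EnrichmentTable):
    """Enrichment table as a DataFrame: amino acid, counts, E_X."""
    import pandas as pd

    rows = [
        {
            "amino_acid": aa,
            "count_conserved": table.counts_conserved.get(aa, 0),
            "count_interface": table.counts_interface.get(aa, 0),
            "e_x": table.e_x.get(aa),
        }
        for aa in sorted(table.counts_interface)
    ]
    return pd.DataFrame(rows, columns=["amino_acid", "count_conserved", "count_interface", "e_x"])
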