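"""Sequence-conservation scoring from a multiple sequence alignment.

Per-column conservation is the Shannon entropy of amino-acid *class*
frequencies, s(i) = -Σ_k p_i(k) ln p_i(k), over a 7-class grouping in which
within-class substitutions are treated as conservative (no penalty):

    1: A V L I M C    2: G S T    3: D E    4: N Q
    5: R K            6: P F Y W  7: H

A relative-entropy (Kullback-Leibler) variant scores the deviation of the
column's class distribution from background class frequencies,
Σ_k p(k) ln(p(k)/p_back(k)), summed over the classes observed in the column.

Conserved interface residues are selected per interface by one of three
criteria of increasing stringency: entropy below the interface mean <s>_int,
below <s>_int - σ, or exactly zero (fully conserved).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}

#: The 7-class amino-acid grouping (1-letter code -> class index 1..7).
DEFAULT_CLASS_SCHEME: dict[str, int] = {
    "A": 1, "V": 1, "L": 1, "I": 1, "M": 1, "C": 1,
    "G": 2, "S": 2, "T": 2,
    "D": 3, "E": 3,
    "N": 4, "Q": 4,
    "R": 5, "K": 5,
    "P": 6, "F": 6, "Y": 6, "W": 6,
    "H": 7,
}

N_CLASSES = 7
MAX_ENTROPY = math.log(N_CLASSES)


class AlignmentError(ValueError):
    """Raised for malformed alignments or failed query-structure mapping."""


class UndefinedColumnError(ValueError):
    """A column has no usable (non-gap, standard) residues; entropy is undefined."""


@dataclass
class Alignment:
    """Equal-length gapped sequences; row ``query_index`` matches the structure."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    query_index: int = 0

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows, lengths {sorted(lengths)}")
        norm = []
        for s in self.sequences:
            s = s.upper().replace(".", "-")
            norm.append(s)
        self.sequences = norm
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        if not 0 <= self.query_index < len(self.sequences):
            raise AlignmentError("query_index out of range")
        nonstandard = {
            ch
            for s in self.sequences
            for ch in s
            if ch not in DEFAULT_CLASS_SCHEME and ch not in GAP_CHARS
        }
        if nonstandard:
            logger.warning(
                "alignment contains nonstandard residue codes %s; "
                "they are excluded from entropy counts", sorted(nonstandard)
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.sequences)

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def query_ungapped(self) -> str:
        return "".join(c for c in self.query if c not in GAP_CHARS)


def read_alignment(path, query_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file ('-' and '.' are gaps; rows must be equal length)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: alignment needs at least 2 sequences, got {len(records)}")
    seqs = [str(r.seq) for r in records]
    ids = [r.id for r in records]
    lengths = sorted({len(s) for s in seqs})
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: ragged alignment rows, lengths {lengths}")
    query_index = 0
    if query_id is not None:
        try:
            query_index = ids.index(query_id)
        except ValueError:
            raise AlignmentError(f"{path}: query id {query_id!r} not found") from None
    return Alignment(sequences=seqs, ids=ids, query_index=query_index)


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{name}\n{seq}\n")


def _class_counts(column: str, scheme: Mapping[str, int]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for ch in column:
        if ch in GAP_CHARS:
            continue
        k = scheme.get(ch)
        if k is None:
            continue  # 'X' and other nonstandard codes are not a class
        counts[k] = counts.get(k, 0) + 1
    return counts


def column_entropy(column: str, scheme: Mapping[str, int] | None = None) -> float:
    """Shannon entropy (nats) of class frequencies in one alignment column.

    Gaps and nonstandard codes are excluded from the counts.  Raises
    :class:`UndefinedColumnError` for a column with no countable residues.
    """
    scheme = DEFAULT_CLASS_SCHEME if scheme is None else scheme
    counts = _class_counts(column, scheme)
    total = sum(counts.values())
    if total == 0:
        raise UndefinedColumnError("column has no non-gap standard residues")
    s = 0.0
    for c in counts.values():
        p = c / total
        s -= p * math.log(p)
    return s


def column_relative_entropy(
    column: str,
    background: Mapping[int, float],
    scheme: Mapping[str, int] | None = None,
) -> float:
    """Kullback-Leibler divergence (nats) of the column's class distribution
    from background class frequencies, over the classes observed in the column."""
    scheme = DEFAULT_CLASS_SCHEME if scheme is None else scheme
    counts = _class_counts(column, scheme)
    total = sum(counts.values())
    if total == 0:
        raise UndefinedColumnError("column has no non-gap standard residues")
    s = 0.0
    for k, c in counts.items():
        p = c / total
        pb = background.get(k, 0.0)
        if pb <= 0.0:
            raise ValueError(f"background frequency for class {k} is zero but the class is observed")
        s += p * math.log(p / pb)
    return s


def background_from_sequences(
    sequences: Iterable[str],
    scheme: Mapping[str, int] | None = None,
    pseudocount: float = 1.0,
) -> dict[int, float]:
    """Background class frequencies from pooled residue strings.

    Additive smoothing (default pseudo-count 1 per class) guarantees every
    class has positive probability.
    """
    scheme = DEFAULT_CLASS_SCHEME if scheme is None else scheme
    counts = {k: 0 for k in range(1, N_CLASSES + 1)}
    n = 0
    for seq in sequences:
        for ch in seq.upper():
            k = scheme.get(ch)
            if k is not None:
                counts[k] += 1
                n += 1
    if n == 0:
        raise ValueError("no standard residues in background input")
    denom = n + pseudocount * N_CLASSES
    return {k: (counts[k] + pseudocount) / denom for k in counts}


def read_background(path) -> dict[int, float]:
    """Read a 7-line 'class probability' key-value table."""
    table: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, p = line.split()
            table[int(k)] = float(p)
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"background probabilities sum to {total}, not 1")
    return table


def write_background(background: Mapping[int, float], path) -> None:
    with open(path, "w") as fh:
        for k in sorted(background):
            fh.write(f"{k} {background[k]:.12g}\n")


def map_query_to_structure(
    alignment: Alignment,
    chain: StructureModel,
    chain_id: str | None = None,
    max_mismatch_frac: float = 0.05,
) -> dict[int, ResidueKey]:
    """Map alignment columns onto structure residues through the query row.

    The query row's ungapped sequence is aligned with the chain's observed
    residue sequence (global alignment, gaps penalised so coordinate gaps are
    handled); columns whose query residue has no counterpart in the
    coordinates are dropped.  Identity mismatches above ``max_mismatch_frac``
    raise an error reporting the first offending positions.
    """
    if chain_id is None:
        ids = chain.chain_ids
        if len(ids) != 1:
            raise AlignmentError(
                f"structure has chains {ids}; pass chain_id to select the mapped chain"
            )
        chain_id = ids[0]
    chain_keys = chain.residue_keys([chain_id])
    chain_seq = chain.sequence(chain_id)
    query_cols = [i for i, ch in enumerate(alignment.query) if ch not in GAP_CHARS]
    query_seq = alignment.query_ungapped()

    if query_seq == chain_seq:
        pairs = list(zip(range(len(query_seq)), range(len(chain_seq))))
    else:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -0.5
        aln = aligner.align(query_seq, chain_seq)[0]
        pairs = []
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            pairs.extend(zip(range(qs, qe), range(ts, te)))

    mismatches = [
        (qi, ti) for qi, ti in pairs if query_seq[qi] != chain_seq[ti]
    ]
    if pairs and len(mismatches) / len(pairs) > max_mismatch_frac:
        detail = ", ".join(
            f"query {qi + 1} {query_seq[qi]} vs chain {chain_keys[ti]} {chain_seq[ti]}"
            for qi, ti in mismatches[:5]
        )
        raise AlignmentError(
            f"query/structure identity mismatch {len(mismatches)}/{len(pairs)} "
            f"exceeds tolerance {max_mismatch_frac:.0%}: {detail}"
        )
    n_unmapped = len(query_seq) - len(pairs)
    if n_unmapped:
        logger.warning(
            "%d query position(s) have no counterpart in the coordinates and are dropped",
            n_unmapped,
        )
    return {query_cols[qi]: chain_keys[ti] for qi, ti in pairs}


@dataclass
class EntropyProfile:
    """Per-residue sequence entropy values mapped onto structure residues."""

    values: dict[ResidueKey, float]
    n_effective: dict[ResidueKey, int]
    kind: str = "plain"  # 'plain' (Shannon) or 'relative' (KL vs background)

    def defined_over(self, keys: Iterable[ResidueKey]) -> set[ResidueKey]:
        return {k for k in keys if k in self.values}


def entropy_profile(
    alignment: Alignment,
    column_map: Mapping[int, ResidueKey],
    kind: str = "plain",
    background: Mapping[int, float] | None = None,
    scheme: Mapping[str, int] | None = None,
    min_rows: int = 2,
) -> EntropyProfile:
    """Compute an entropy profile over the mapped columns.

    Columns with fewer than ``min_rows`` countable residues are excluded
    (undefined) rather than reported as spuriously conserved.
    """
    if kind not in ("plain", "relative"):
        raise ValueError(f"unknown entropy kind {kind!r}")
    if kind == "relative" and background is None:
        raise ValueError("relative entropy requires background frequencies")
    scheme = DEFAULT_CLASS_SCHEME if scheme is None else scheme
    values: dict[ResidueKey, float] = {}
    n_eff: dict[ResidueKey, int] = {}
    n_skipped = 0
    for col, key in column_map.items():
        column = alignment.column(col)
        counts = _class_counts(column, scheme)
        total = sum(counts.values())
        if total < min_rows:
            n_skipped += 1
            continue
        if kind == "plain":
            values[key] = column_entropy(column, scheme)
        else:
            values[key] = column_relative_entropy(column, background, scheme)
        n_eff[key] = total
    if n_skipped:
        logger.warning(
            "%d column(s) with fewer than %d usable rows excluded from the profile",
            n_skipped, min_rows,
        )
    return EntropyProfile(values=values, n_effective=n_eff, kind=kind)


CRITERIA = ("mean", "mean-sd", "zero")
_CRITERION_ALIASES = {
    "mean": "mean", "below-mean": "mean",
    "mean-sd": "mean-sd", "below-mean-minus-sd": "mean-sd",
    "zero": "zero", "zero-entropy": "zero",
}
ZERO_TOL = 1e-12


@dataclass
class ConservedSet:
    """Residues selected as conserved under a stated criterion.

    For the plain-entropy criteria, selection is relative to the mean (and SD)
    of the entropies over the evaluated residue set itself.
    """

    members: set[ResidueKey]
    criterion: str
    mean_entropy: float
    sd_entropy: float


def select_conserved(
    profile: EntropyProfile,
    over: Iterable[ResidueKey],
    criterion: str = "mean",
) -> ConservedSet:
    """Select conserved residues from ``over`` under one of three criteria:

    - ``mean``:    s(i) <  <s>          (strictly below the mean)
    - ``mean-sd``: s(i) <  <s> - σ
    - ``zero``:    s(i) == 0 (within 1e-12)
    """
    try:
        criterion = _CRITERION_ALIASES[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; use one of {CRITERIA}") from None
    over = list(over)
    if not over:
        raise ValueError("cannot select conserved residues from an empty set")
    missing = [k for k in over if k not in profile.values]
    if missing:
        raise ValueError(f"entropy undefined for residues: {missing[:5]}")
    s = np.array([profile.values[k] for k in over])
    mean = float(s.mean())
    sd = float(s.std(ddof=0))
    # strict '<' with a small guard so values equal to the cutoff up to
    # floating-point error are not selected
    eps = 1e-12 * max(1.0, abs(mean))
    if criterion == "mean":
        members = {k for k, v in zip(over, s) if v < mean - eps}
    elif criterion == "mean-sd":
        members = {k for k, v in zip(over, s) if v < mean - sd - eps}
    else:
        members = {k for k, v in zip(over, s) if abs(v) <= ZERO_TOL}
    return ConservedSet(members=members, criterion=criterion, mean_entropy=mean, sd_entropy=sd)


def profile_report_frame(
    profile: EntropyProfile, model: StructureModel, keys: Sequence[ResidueKey] | None = None
):
    """Entropy profile as a DataFrame: chain, resnum, icode, resname, entropy, n_effective."""
    import pandas as pd

    if keys is None:
        keys = sorted(profile.values)
    rows = [
        {
            "chain": k.chain_id,
            "resnum": k.residue_number,
            "icode": k.insertion_code,
            "resname": model.residue_name(k),
            "entropy": profile.values[k],
            "n_effective": profile.n_effective[k],
        }
        for k in keys
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname", "entropy", "n_effective"])
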