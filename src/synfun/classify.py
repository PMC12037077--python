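"""Paralog assignment by distance to labeled references, and gene-status
calls (present / pseudogenized / absent) from exon presence maps.

Paralog assignment operationalizes "clear sequence identity between the two
paralog families" as nearest-reference-set classification: the query's mean
proportional mismatch distance (mismatches / compared columns, gaps
pairwise-deleted) to each labeled reference family is computed and the
closest family wins.  Exact ties yield the label ``ambiguous``.

Gene status distinguishes ``absent`` (assayed and not found — an input
assertion, typically from synteny evidence) from ``no-data`` (locus not
assayed); a gene with any missing or modified reference exon, or with an
intact-exon fraction below threshold, is called ``pseudogenized``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GAP,
    AlignedSequenceSet,
    Cladogram,
    DEFAULT_REF_EXON_COUNT,
    EXON_PRESENT,
    ExonMap,
    SchemaError,
    SequenceRecord,
)

AMBIGUOUS = "ambiguous"

STATUS_PRESENT = "present"
STATUS_PSEUDOGENIZED = "pseudogenized"
STATUS_ABSENT = "absent"
STATUS_NO_DATA = "no-data"


@dataclass(frozen=True)
class ParalogCall:
    """Nearest-reference-set assignment of one query sequence."""

    query_id: str
    label: str                          # best label, or "ambiguous" on ties
    mean_distances: dict[str, float]    # label -> mean proportional distance
    margin: float                       # second best - best (>= 0)
    confident: bool

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


def _pair_distance(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared columns) under pairwise gap deletion."""
    xa = np.frombuffer(a.encode("ascii"), dtype="S1")
    xb = np.frombuffer(b.encode("ascii"), dtype="S1")
    comp = (xa != GAP.encode()) & (xb != GAP.encode())
    return int(((xa != xb) & comp).sum()), int(comp.sum())


def assign_paralog(
    query: SequenceRecord,
    refs: AlignedSequenceSet,
    margin_threshold: float = 0.05,
) -> ParalogCall:
    """Assign ``query`` to the paralog family of its nearest reference set.

    ``refs`` must carry a ``paralog`` label on every record and share
    alignment coordinates with the query.  References sharing zero compared
    columns with the query are excluded (with a warning); a label whose
    references are all excluded is dropped.  The call is ``confident`` when
    the margin between the best and second-best family reaches
    ``margin_threshold`` (proportion of compared columns, default 5%).
    """
    if len(query.residues) != refs.n_columns:
        raise ValueError(
            f"query {query.id!r} length {len(query.residues)} does not match "
            f"reference alignment columns {refs.n_columns}"
        )
    by_label: dict[str, list[float]] = {}
    excluded = 0
    for ref in refs:
        if ref.paralog is None:
            raise ValueError(f"reference {ref.id!r} lacks a paralog label")
        mism, ncomp = _pair_distance(query.residues, ref.residues)
        if ncomp == 0:
            excluded += 1
            continue
        by_label.setdefault(ref.paralog, []).append(mism / ncomp)
    if excluded:
        warnings.warn(
            f"{excluded} reference(s) shared zero compared columns with "
            f"query {query.id!r} and were excluded",
            stacklevel=2,
        )
    if not by_label:
        raise ValueError(
            f"query {query.id!r} has zero compared columns against every "
            "reference set"
        )
    means = {lab: float(np.mean(v)) for lab, v in by_label.items()}
    ordered = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    best_label, best = ordered[0]
    if len(ordered) == 1:
        return ParalogCall(query.id, best_label, means, margin=0.0, confident=False)
    second = ordered[1][1]
    margin = second - best
    if margin == 0.0:
        return ParalogCall(query.id, AMBIGUOUS, means, margin=0.0, confident=False)
    return ParalogCall(
        query.id, best_label, means,
        margin=margin, confident=margin >= margin_threshold,
    )


# ---------------------------------------------------------------------------
# gene status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneStatusRecord:
    """Present / pseudogenized / absent call for one species x paralog."""

    species: str
    paralog: str
    status: str
    missing_exons: tuple[int, ...]   # 1-based exon numbers not intact
    fraction_intact: float

    def __post_init__(self) -> None:
        if self.status not in (STATUS_PRESENT, STATUS_PSEUDOGENIZED, STATUS_ABSENT):
            raise ValueError(f"invalid status {self.status!r}")
        if not 0.0 <= self.fraction_intact <= 1.0:
            raise ValueError("fraction_intact must lie in [0, 1]")


def classify_gene_status(
    exon_map: ExonMap | None,
    species: str | None = None,
    paralog: str | None = None,
    ref_exon_count: int = DEFAULT_REF_EXON_COUNT,
    intact_threshold: float = 0.9,
) -> GeneStatusRecord:
    """Call gene status from an exon map.

    ``exon_map=None`` encodes an explicit absence record (``species`` and
    ``paralog`` must then be supplied).  A gene is ``pseudogenized`` when any
    reference exon is missing or modified ("modified" = present but not
    homologous, which counts as not intact) or when the intact fraction falls
    below ``intact_threshold``; otherwise ``present``.
    """
    if exon_map is None:
        if species is None or paralog is None:
            raise ValueError("absent record needs explicit species and paralog")
        return GeneStatusRecord(
            species=species, paralog=paralog, status=STATUS_ABSENT,
            missing_exons=tuple(range(1, ref_exon_count + 1)),
            fraction_intact=0.0,
        )
    if exon_map.n_exons != ref_exon_count:
        raise SchemaError(
            f"{exon_map.species}/{exon_map.paralog}: exon map has "
            f"{exon_map.n_exons} exons, expected {ref_exon_count}"
        )
    not_intact = tuple(
        i + 1 for i, s in enumerate(exon_map.exon_status) if s != EXON_PRESENT
    )
    frac = 1.0 - len(not_intact) / ref_exon_count
    status = (
        STATUS_PRESENT
        if not not_intact and frac >= intact_threshold
        else STATUS_PSEUDOGENIZED
    )
    return GeneStatusRecord(
        species=exon_map.species, paralog=exon_map.paralog, status=status,
        missing_exons=not_intact, fraction_intact=frac,
    )


def status_matrix(
    records: list[GeneStatusRecord],
    tree: Cladogram,
    paralogs: list[str] | None = None,
) -> pd.DataFrame:
    """Complete leaf x paralog status table.

    Cells without a record are ``no-data`` (distinct from ``absent``, which
    must be asserted by an explicit record).  Species not on the tree raise.
    """
    leaves = tree.leaf_names
    leaf_set = set(leaves)
    offenders = sorted({r.species for r in records} - leaf_set)
    if offenders:
        raise KeyError(f"species not on tree: {offenders}")
    if paralogs is None:
        paralogs = sorted({r.paralog for r in records})
    mat = pd.DataFrame(STATUS_NO_DATA, index=leaves, columns=paralogs)
    for r in records:
        if r.paralog in mat.columns:
            mat.loc[r.species, r.paralog] = r.status
    mat.index.name = "species"
    return mat
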