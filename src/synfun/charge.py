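"""Protein net-charge profiling and between-group comparisons.

Charge scheme: aspartate and glutamate count as a single negative charge
(-1), arginine, histidine and lysine as a single positive charge (+1), and
every other residue (including unknown 'X' and gaps) as 0.  Histidine is
deliberately counted +1 under this scheme even though its physiological pKa
makes it only partially protonated; the integer scheme keeps region scores
directly interpretable as a net count of charged residues.

Region-wise net charge (``n_pos - n_neg``) is summarized per sequence, the
acidic C-terminal tail can be detected and truncated, and groups of
sequences (e.g. clades) are compared with pairwise Welch t-tests under a
Bonferroni correction over all group pairs, with the usual significance
tiers (* / ** / *** at corrected p < 0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ALLOWED_RESIDUES,
    GAP,
    AlignedSequenceSet,
    RegionMap,
    SequenceRecord,
)

NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("RHK")

_CHARGE = {c: 0 for c in ALLOWED_RESIDUES}
_CHARGE.update({c: -1 for c in NEGATIVE_RESIDUES})
_CHARGE.update({c: +1 for c in POSITIVE_RESIDUES})

TIER_NS = "ns"
TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def residue_charge(residue: str) -> int:
    """Charge of a single residue: D/E -> -1, R/H/K -> +1, others (incl.
    'X' and '-') -> 0."""
    try:
        return _CHARGE[residue]
    except KeyError:
        raise ValueError(f"disallowed residue character {residue!r}") from None


@dataclass(frozen=True)
class ChargeTrack:
    """Per-alignment-column charge values for one sequence; gap columns are
    flagged and always carry charge 0."""

    id: str
    values: np.ndarray        # int8, in {-1, 0, +1}
    gap_mask: np.ndarray      # bool, True at gap columns

    def __post_init__(self) -> None:
        if self.values.shape != self.gap_mask.shape:
            raise ValueError("values and gap_mask shapes differ")
        if np.any(self.values[self.gap_mask] != 0):
            raise ValueError("gap positions must carry charge 0")


def charge_track(record: SequenceRecord) -> ChargeTrack:
    arr = np.frombuffer(record.residues.encode("ascii"), dtype="S1")
    values = np.zeros(arr.size, dtype=np.int8)
    for res in NEGATIVE_RESIDUES:
        values[arr == res.encode()] = -1
    for res in POSITIVE_RESIDUES:
        values[arr == res.encode()] = 1
    gap_mask = arr == GAP.encode()
    return ChargeTrack(id=record.id, values=values, gap_mask=gap_mask)


@dataclass(frozen=True)
class RegionChargeSummary:
    """Net charge of one sequence over one region of alignment columns."""

    id: str
    region: str
    net_charge: int
    n_neg: int
    n_pos: int
    n_residues: int

    def __post_init__(self) -> None:
        if self.net_charge != self.n_pos - self.n_neg:
            raise ValueError("net_charge must equal n_pos - n_neg")
        if self.n_neg + self.n_pos > self.n_residues:
            raise ValueError("charged residues exceed residue count")

    @property
    def net_charge_per_residue(self) -> float:
        return self.net_charge / self.n_residues if self.n_residues else float("nan")


def net_charge(
    record: SequenceRecord,
    region: tuple[int, int],
    region_name: str = "whole",
) -> RegionChargeSummary:
    """Count charged residues of ``record`` over alignment columns
    ``[start, end)``; gaps contribute nothing."""
    start, end = region
    n_cols = len(record.residues)
    if not (0 <= start < end <= n_cols):
        raise ValueError(f"region [{start}, {end}) empty or outside [0, {n_cols})")
    window = record.residues[start:end]
    n_neg = sum(window.count(c) for c in NEGATIVE_RESIDUES)
    n_pos = sum(window.count(c) for c in POSITIVE_RESIDUES)
    n_res = len(window) - window.count(GAP)
    return RegionChargeSummary(
        id=record.id, region=region_name,
        net_charge=n_pos - n_neg, n_neg=n_neg, n_pos=n_pos, n_residues=n_res,
    )


def region_charge_summaries(
    aln: AlignedSequenceSet, region_map: RegionMap
) -> list[RegionChargeSummary]:
    """Net-charge summary for every sequence x region combination."""
    return [
        net_charge(rec, region_map[name], name)
        for rec in aln
        for name in region_map.names()
    ]


def summaries_to_frame(summaries: Sequence[RegionChargeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": s.id, "region": s.region, "net_charge": s.net_charge,
                "n_neg": s.n_neg, "n_pos": s.n_pos, "n_residues": s.n_residues,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# acidic tail
# ---------------------------------------------------------------------------

def detect_acidic_tail(
    record: SequenceRecord,
    min_len: int = 5,
    min_acidic_frac: float = 0.7,
) -> tuple[int, int]:
    """Locate the acidic C-terminal tail of the ungapped sequence.

    Returns ``(start, end)`` over ungapped residue positions (0-based
    half-open) of the longest suffix whose D/E fraction is at least
    ``min_acidic_frac`` and whose length is at least ``min_len``; returns the
    empty interval ``(n, n)`` when no suffix qualifies.
    """
    seq = record.ungapped
    n = len(seq)
    is_acidic = np.frombuffer(seq.encode("ascii"), dtype="S1")
    acidic = (is_acidic == b"D") | (is_acidic == b"E")
    # cumulative acidic counts of each suffix, longest first
    suffix_counts = np.cumsum(acidic[::-1])
    for length in range(n, max(min_len, 1) - 1, -1):
        if suffix_counts[length - 1] / length >= min_acidic_frac:
            return (n - length, n)
    return (n, n)


def truncate_tail(
    aln: AlignedSequenceSet,
    min_len: int = 5,
    min_acidic_frac: float = 0.7,
    consensus: float = 0.5,
) -> AlignedSequenceSet:
    """Remove acidic-tail columns from the alignment.

    A column is removed when it falls inside the detected tail of at least
    ``consensus`` (default 50%) of the records that are non-gap at that
    column.  The input set is not modified.
    """
    n_cols = aln.n_columns
    in_tail = np.zeros((len(aln.records), n_cols), dtype=bool)
    non_gap = np.zeros_like(in_tail)
    for i, rec in enumerate(aln.records):
        arr = np.frombuffer(rec.residues.encode("ascii"), dtype="S1")
        mask = arr != GAP.encode()
        non_gap[i] = mask
        tail_start, tail_end = detect_acidic_tail(rec, min_len, min_acidic_frac)
        if tail_end > tail_start:
            cols = np.flatnonzero(mask)       # ungapped position -> column
            in_tail[i, cols[tail_start:tail_end]] = True
    n_non_gap = non_gap.sum(axis=0)
    n_in_tail = in_tail.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_non_gap > 0, n_in_tail / np.maximum(n_non_gap, 1), 0.0)
    keep = frac < consensus
    if keep.all():
        return aln
    from dataclasses import replace
    kept_cols = np.flatnonzero(keep)
    new_records = tuple(
        replace(rec, residues="".join(rec.residues[c] for c in kept_cols))
        for rec in aln.records
    )
    return AlignedSequenceSet(new_records)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    """Welch t-test of net charge between two groups, Bonferroni-corrected
    over all pairs compared together."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t: float
    p_raw: float
    p_corrected: float
    tier: str


def _tier(p_corrected: float) -> str:
    for cutoff, label in TIERS:
        if p_corrected < cutoff:
            return label
    return TIER_NS


def welch_t(
    a: np.ndarray, b: np.ndarray, variance_floor: float | None = None
) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p value.

    Zero within-group variances (degenerate but legal inputs, e.g. identical
    replicates) are floored at machine-epsilon scale so that a clear mean
    difference still registers instead of producing 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if variance_floor is None:
        scale = max(1.0, abs(a.mean()), abs(b.mean())) ** 2
        variance_floor = np.finfo(float).eps * scale
    if va <= variance_floor or vb <= variance_floor:
        if va == 0 or vb == 0:
            warnings.warn(
                "zero within-group variance floored at machine-epsilon scale",
                stacklevel=2,
            )
        va = max(va, variance_floor)
        vb = max(vb, variance_floor)
    se2 = va / n_a + vb / n_b
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def compare_group_values(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[GroupComparisonResult]:
    """All unordered pairwise Welch t-tests with Bonferroni correction.

    Pairs involving a group with fewer than 2 values are skipped with a
    warning; the correction multiplier is the number of pairs actually
    tested.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    usable = [g for g in groups if groups[g].size >= 2]
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"groups with <2 values skipped: {skipped}", stacklevel=2)
    pairs = list(itertools.combinations(sorted(usable), 2))
    n_pairs = len(pairs)
    results = []
    for ga, gb in pairs:
        t, p_raw = welch_t(groups[ga], groups[gb])
        p_corr = min(1.0, p_raw * n_pairs)
        results.append(
            GroupComparisonResult(
                group_a=ga, group_b=gb,
                n_a=groups[ga].size, n_b=groups[gb].size,
                t=t, p_raw=p_raw, p_corrected=p_corr, tier=_tier(p_corr),
            )
        )
    return results


def compare_groups(
    summaries: Iterable[RegionChargeSummary],
    grouping: Mapping[str, str],
    region: str,
    per_residue: bool = False,
) -> list[GroupComparisonResult]:
    """Compare region net charges between groups of sequences.

    ``grouping`` maps sequence id to group label (e.g. clade); summaries not
    in ``grouping`` are ignored.  ``per_residue=True`` compares net charge
    per non-gap residue instead of raw net charge.
    """
    values: dict[str, list[float]] = {}
    for s in summaries:
        if s.region != region or s.id not in grouping:
            continue
        v = s.net_charge_per_residue if per_residue else float(s.net_charge)
        values.setdefault(grouping[s.id], []).append(v)
    return compare_group_values(values)


def comparisons_to_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a, "group_b": r.group_b,
                "n_a": r.n_a, "n_b": r.n_b, "t": r.t,
                "p_raw": r.p_raw, "p_corrected": r.p_corrected, "tier": r.tier,
            }
            for r in results
        ]
    )
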