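"""Paralog expression shares, tissue dominance states, and tree-based
detection of dominance shifts (synfunctionalization candidates).

Pipeline: per-sample cpm values are aggregated to species x tissue x paralog
means, normalized to family shares (each paralog's fraction of the family's
total cpm), and turned into categorical dominance states (the paralog holding
a strict majority share above an expression floor).  Dominance states are
then mapped onto the species cladogram with small parsimony, and the
branches on which the state must (or may) change are reported as shift
events.  A change required by *every* most-parsimonious reconstruction is
flagged unambiguous; changes present in only some reconstructions are
flagged ambiguous rather than averaged away.

The minimum change count uses Hartigan's generalization of Fitch parsimony
(exact on multifurcating rooted trees); per-branch change status is decided
exactly with a unit-cost dynamic program over subtree/context costs, not by
enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .charge import GroupComparisonResult
from .io import Cladogram, ExpressionRecord, expression_to_frame
from .classify import (
    AMBIGUOUS,
    STATUS_ABSENT,
    STATUS_NO_DATA,
    STATUS_PSEUDOGENIZED,
)

NO_DATA = STATUS_NO_DATA
_INF = math.inf

SHARE_TOLERANCE = 1e-9


# ---------------------------------------------------------------------------
# shares
# ---------------------------------------------------------------------------

def compute_shares(
    records: Sequence[ExpressionRecord], agg: str = "mean"
) -> pd.DataFrame:
    """Family-normalized expression shares per species x tissue x paralog.

    Sample cpm values are aggregated per paralog (mean by default, median by
    ``agg="median"``), summed to the family total, and normalized.  When the
    family total is zero the share is NaN (undefined), never 0/0.

    Returns a DataFrame with columns ``species, tissue, paralog, mean_cpm,
    family_cpm, share``.
    """
    if not records:
        raise ValueError("no expression records")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    df = expression_to_frame(records)
    per_paralog = (
        df.groupby(["species", "tissue", "paralog"], as_index=False)["cpm"]
        .agg(agg)
        .rename(columns={"cpm": "mean_cpm"})
    )
    family = (
        per_paralog.groupby(["species", "tissue"], as_index=False)["mean_cpm"]
        .sum()
        .rename(columns={"mean_cpm": "family_cpm"})
    )
    out = per_paralog.merge(family, on=["species", "tissue"])
    out["share"] = np.where(
        out["family_cpm"] > 0, out["mean_cpm"] / out["family_cpm"], np.nan
    )
    return out.sort_values(["species", "tissue", "paralog"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceState:
    """The dominant paralog of one species x tissue, or ambiguous/no-data."""

    species: str
    tissue: str
    state: str          # paralog label, "ambiguous", or "no-data"
    share: float        # share of the dominant paralog (NaN if undefined)
    family_cpm: float


def call_dominance(
    shares: pd.DataFrame,
    threshold: float = 0.5,
    floor_cpm: float = 10.0,
    species_universe: Iterable[str] | None = None,
    tissues: Iterable[str] | None = None,
) -> list[DominanceState]:
    """Call the dominant paralog per species x tissue.

    A paralog is dominant when its share strictly exceeds ``threshold`` and
    the family total reaches ``floor_cpm`` (dominance is never called from
    noise-level family expression); otherwise the state is ``ambiguous``.
    If ``species_universe``/``tissues`` are given, combinations missing from
    ``shares`` are emitted as explicit ``no-data`` states.
    """
    states: list[DominanceState] = []
    seen: set[tuple[str, str]] = set()
    for (sp, tissue), grp in shares.groupby(["species", "tissue"]):
        seen.add((sp, tissue))
        family = float(grp["family_cpm"].iloc[0])
        if family <= 0 or not np.isfinite(family):
            states.append(DominanceState(sp, tissue, AMBIGUOUS, float("nan"), family))
            continue
        best = grp.loc[grp["share"].idxmax()]
        share = float(best["share"])
        if share > threshold and family >= floor_cpm:
            state = str(best["paralog"])
        else:
            state = AMBIGUOUS
        states.append(DominanceState(sp, tissue, state, share, family))
    if species_universe is not None and tissues is not None:
        for sp in species_universe:
            for tissue in tissues:
                if (sp, tissue) not in seen:
                    states.append(
                        DominanceState(sp, tissue, NO_DATA, float("nan"), 0.0)
                    )
    states.sort(key=lambda s: (s.species, s.tissue))
    return states


def dominance_to_frame(states: Sequence[DominanceState]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species, "tissue": s.tissue, "state": s.state,
                "share": s.share, "family_cpm": s.family_cpm,
            }
            for s in states
        ]
    )


# ---------------------------------------------------------------------------
# small parsimony
# ---------------------------------------------------------------------------

def fitch_min_changes(
    tree: Cladogram, leaf_states: Mapping[str, str]
) -> tuple[int, dict[str, frozenset[str]]]:
    """Exact minimum number of state changes on a rooted cladogram
    (Hartigan's generalization of Fitch parsimony, valid for
    multifurcations), plus the per-node preferred state sets of the
    bottom-up pass.

    Leaves absent from ``leaf_states`` are excluded by pruning the tree
    first.  The state alphabet is the set of observed leaf states.
    """
    alphabet = sorted(set(leaf_states.values()))
    if not alphabet:
        raise ValueError("empty state alphabet")
    work = tree
    if set(leaf_states) != set(tree.leaf_names):
        missing = set(leaf_states) - set(tree.leaf_names)
        if missing:
            raise KeyError(f"leaf states for unknown leaves: {sorted(missing)}")
        work = tree.pruned_to(leaf_states.keys())
    changes = 0
    node_sets: dict[str, frozenset[str]] = {}
    pref: dict[int, frozenset[str]] = {}
    for nd in work.postorder():
        if nd.is_leaf():
            s = frozenset([leaf_states[nd.taxon.label]])
        else:
            votes: dict[str, int] = {}
            children = nd.child_nodes()
            for c in children:
                for st in pref[id(c)]:
                    votes[st] = votes.get(st, 0) + 1
            top = max(votes.values())
            s = frozenset(st for st, v in votes.items() if v == top)
            changes += len(children) - top
        pref[id(nd)] = s
        node_sets[work.node_label(nd)] = s
    return changes, node_sets


def _unit_cost_dp(
    work: Cladogram, leaf_states: Mapping[str, str], alphabet: Sequence[str]
) -> tuple[float, dict, dict]:
    """Down (subtree) and context (rest-of-tree) unit-cost parsimony tables.

    Returns ``(min_total, down, ctx_excl)`` where ``down[id(v)][s]`` is the
    minimum changes within v's subtree given v has state s, and
    ``ctx_excl[id(v)][s]`` is the minimum changes outside v's subtree given
    v's *parent* has state s (the branch to v excluded).
    """
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    down: dict[int, np.ndarray] = {}
    dedge: dict[int, np.ndarray] = {}  # min over child state + change indicator

    for nd in work.postorder():
        if nd.is_leaf():
            v = np.full(k, _INF)
            v[idx[leaf_states[nd.taxon.label]]] = 0.0
        else:
            v = np.zeros(k)
            for c in nd.child_nodes():
                v += dedge[id(c)]
        down[id(nd)] = v
        dedge[id(nd)] = np.minimum(v, 1.0 + v.min())

    root = work.tree.seed_node
    min_total = float(down[id(root)].min())

    ctx_excl: dict[int, np.ndarray] = {}
    ctx: dict[int, np.ndarray] = {id(root): np.zeros(k)}
    for nd in work.preorder():
        for child in nd.child_nodes():
            g = ctx[id(nd)].copy()
            for sib in nd.child_nodes():
                if sib is not child:
                    g += dedge[id(sib)]
            ctx_excl[id(child)] = g
            ctx[id(child)] = np.minimum(g, 1.0 + g.min())
    return min_total, down, ctx_excl


@dataclass(frozen=True)
class ShiftEvent:
    """A dominance-state change on one branch (identified by its child
    node's label on the input tree) for one tissue."""

    branch: str
    tissue: str
    from_state: str
    to_state: str
    unambiguous: bool            # change required by every MPR
    clade_leaves: frozenset[str]

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("from_state and to_state must differ")


def detect_shift_events(
    dominance: Sequence[DominanceState],
    tree: Cladogram,
    tissue: str,
    exclude_states: frozenset[str] = frozenset({AMBIGUOUS, NO_DATA}),
) -> list[ShiftEvent]:
    """Branches on which the tissue's dominance state changes in
    most-parsimonious reconstructions.

    Leaves whose state is ambiguous or no-data are pruned before parsimony
    (they carry no usable signal and are never treated as a free state).
    An event is emitted for every branch that changes in at least one MPR;
    ``unambiguous`` is True when the branch changes in *all* MPRs.  From/to
    states are the parsimony-optimal assignments across that branch (joined
    with ``|`` when several pairs are tied).
    """
    leaf_states = {
        d.species: d.state
        for d in dominance
        if d.tissue == tissue and d.state not in exclude_states
    }
    leaf_states = {
        sp: st for sp, st in leaf_states.items() if sp in set(tree.leaf_names)
    }
    if len(leaf_states) < 2:
        warnings.warn(
            f"tissue {tissue!r}: fewer than 2 usable dominance states; "
            "no events detectable",
            stacklevel=2,
        )
        return []
    alphabet = sorted(set(leaf_states.values()))
    if len(alphabet) < 2:
        return []
    work = tree.pruned_to(leaf_states.keys())
    min_total, down, ctx_excl = _unit_cost_dp(work, leaf_states, alphabet)

    events: list[ShiftEvent] = []
    for nd in work.preorder():
        for child in nd.child_nodes():
            g = ctx_excl[id(child)]
            d = down[id(child)]
            min_eq = float((g + d).min())
            # cheapest assignment with a change across this branch
            pair_costs = g[:, None] + d[None, :] + 1.0
            np.fill_diagonal(pair_costs, _INF)
            min_diff = float(pair_costs.min())
            if min_diff != min_total:
                continue  # no MPR changes on this branch
            winners = np.argwhere(pair_costs == min_total)
            pairs = sorted(
                (alphabet[i], alphabet[j]) for i, j in winners
            )
            from_state = "|".join(sorted({p[0] for p in pairs}))
            to_state = "|".join(sorted({p[1] for p in pairs}))
            clade = work.clade_leaves(child)
            branch_node = tree.mrca(clade) if len(clade) > 1 else (
                tree.find_node(next(iter(clade)))
            )
            events.append(
                ShiftEvent(
                    branch=tree.node_label(branch_node),
                    tissue=tissue,
                    from_state=from_state,
                    to_state=to_state,
                    unambiguous=min_eq > min_total,
                    clade_leaves=clade,
                )
            )
    events.sort(key=lambda e: (len(e.clade_leaves), e.branch))
    return events


def events_to_frame(events: Sequence[ShiftEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch": e.branch, "tissue": e.tissue,
                "from_state": e.from_state, "to_state": e.to_state,
                "unambiguous": e.unambiguous,
                "n_clade_species": len(e.clade_leaves),
                "clade_species": ",".join(sorted(e.clade_leaves)),
            }
            for e in events
        ],
        columns=[
            "branch", "tissue", "from_state", "to_state", "unambiguous",
            "n_clade_species", "clade_species",
        ],
    )


# ---------------------------------------------------------------------------
# synfunctionalization report
# ---------------------------------------------------------------------------

_TIER_RANK = {"ns": 0, "*": 1, "**": 2, "***": 3}


def _best_tier_for_group(
    comparisons: Sequence[GroupComparisonResult], group: str
) -> str:
    tiers = [
        c.tier for c in comparisons if group in (c.group_a, c.group_b)
    ]
    if not tiers:
        return "ns"
    return max(tiers, key=lambda t: _TIER_RANK[t])


def synfunctionalization_report(
    skeletal_events: Sequence[ShiftEvent],
    cardiac_events: Sequence[ShiftEvent],
    status: pd.DataFrame,
    charge_comparisons: Mapping[str, Sequence[GroupComparisonResult]],
    tree: Cladogram,
    clade_of: Mapping[str, str],
    shares: pd.DataFrame | None = None,
    skeletal_tissue: str = "skeletal",
    cardiac_tissue: str = "cardiac",
) -> pd.DataFrame:
    """Join the three evidence lines per shift event, without asserting
    causality.

    For each expression shift event, the report lists (i) the branch and the
    from/to dominance states, (ii) gene-status decay of the displaced
    paralog among the species below the branch, and (iii) the peak
    significance tier of the region charge comparisons involving the
    shifted clade's group.  If ``shares`` is supplied, the gaining paralog's
    skeletal/cardiac mean-cpm ratio within the shifted clade is included;
    that ratio assumes cross-tissue cpm comparability, which is flagged.
    """
    rows = []
    for event in list(skeletal_events) + list(cardiac_events):
        clade = sorted(event.clade_leaves)
        displaced = event.from_state.split("|")[0]
        gained = event.to_state.split("|")[0]
        if displaced in status.columns:
            sub = status.loc[[sp for sp in clade if sp in status.index], displaced]
            n_pseudo = int((sub == STATUS_PSEUDOGENIZED).sum())
            n_absent = int((sub == STATUS_ABSENT).sum())
        else:
            n_pseudo = n_absent = 0
        decay = n_pseudo + n_absent > 0
        clade_groups = [clade_of[sp] for sp in clade if sp in clade_of]
        group = (
            max(set(clade_groups), key=clade_groups.count) if clade_groups else ""
        )
        tier_by_region = {
            region: _best_tier_for_group(comps, group)
            for region, comps in charge_comparisons.items()
        }
        ratio = float("nan")
        if shares is not None:
            sk = shares[
                (shares["tissue"] == skeletal_tissue)
                & (shares["paralog"] == gained)
                & (shares["species"].isin(clade))
            ]["mean_cpm"]
            ca = shares[
                (shares["tissue"] == cardiac_tissue)
                & (shares["paralog"] == gained)
                & (shares["species"].isin(clade))
            ]["mean_cpm"]
            if len(sk) and len(ca) and ca.mean() > 0:
                ratio = float(sk.mean() / ca.mean())
        rows.append(
            {
                "branch": event.branch,
                "tissue": event.tissue,
                "from_state": event.from_state,
                "to_state": event.to_state,
                "unambiguous": event.unambiguous,
                "n_clade_species": len(clade),
                "n_displaced_pseudogenized": n_pseudo,
                "n_displaced_absent": n_absent,
                "decay": "decay observed" if decay else "no decay observed",
                "clade_group": group,
                **{f"{r}_tier": t for r, t in tier_by_region.items()},
                "skeletal_cardiac_ratio": ratio,
                "ratio_assumption": "assumes cross-tissue cpm comparability",
            }
        )
    return pd.DataFrame(rows)
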