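import itertools
import math

import numpy as np
import pytest

from synfun import Cladogram, ExpressionRecord
from synfun.shift import (
    NO_DATA,
    DominanceState,
    call_dominance,
    compute_shares,
    detect_shift_events,
    events_to_frame,
    fitch_min_changes,
    synfunctionalization_report,
)
from synfun.classify import AMBIGUOUS, classify_gene_status, status_matrix
from synfun.charge import compare_groups, region_charge_summaries
from synfun.simulate import (
    ExonDeletionSpec,
    ScenarioConfig,
    _bisect,
    _to_newick,
    simulate_expression,
    simulate_scenario,
    simulate_tree,
)


# ---------------------------------------------------------------------------
# oracles & helpers
# ---------------------------------------------------------------------------

def brute_force_min_changes(tree: Cladogram, leaf_states: dict[str, str]) -> int:
    """Exhaustive enumeration over all internal-node labelings."""
    states = sorted(set(leaf_states.values()))
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    best = math.inf
    for assignment in itertools.product(states, repeat=len(internals)):
        lab = {id(nd): s for nd, s in zip(internals, assignment)}
        for nd in nodes:
            if nd.is_leaf():
                lab[id(nd)] = leaf_states[nd.taxon.label]
        changes = sum(
            1
            for nd in nodes
            if nd.parent_node is not None
            and lab[id(nd)] != lab[id(nd.parent_node)]
        )
        best = min(best, changes)
    return best


def brute_force_edge_changes(
    tree: Cladogram, leaf_states: dict[str, str]
) -> dict[str, tuple[bool, bool]]:
    """Per branch (child label): (changes in some MPR, changes in all MPRs)."""
    states = sorted(set(leaf_states.values()))
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    best = brute_force_min_changes(tree, leaf_states)
    some: dict[str, bool] = {}
    always: dict[str, bool] = {}
    for assignment in itertools.product(states, repeat=len(internals)):
        lab = {id(nd): s for nd, s in zip(internals, assignment)}
        for nd in nodes:
            if nd.is_leaf():
                lab[id(nd)] = leaf_states[nd.taxon.label]
        changed = {
            tree.node_label(nd): lab[id(nd)] != lab[id(nd.parent_node)]
            for nd in nodes if nd.parent_node is not None
        }
        if sum(changed.values()) != best:
            continue
        for br, ch in changed.items():
            some[br] = some.get(br, False) or ch
            always[br] = always.get(br, True) and ch
    return {br: (some[br], always[br]) for br in some}


def random_tree(n_leaves: int, rng: np.random.Generator) -> Cladogram:
    labels = [f"t{i}" for i in range(n_leaves)]
    return Cladogram.from_newick(_to_newick(_bisect(labels, rng)) + ";")


def expr(species, tissue, paralog, cpm, sample="s1"):
    return ExpressionRecord(species, tissue, paralog, sample, cpm=cpm)


# ---------------------------------------------------------------------------
# shares
# ---------------------------------------------------------------------------

class TestComputeShares:
    def test_simple_split(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 250.0),
            expr("sp", "skeletal", "CASQ2", 750.0),
        ])
        by = shares.set_index("paralog")["share"]
        assert by["CASQ1"] == pytest.approx(0.25)
        assert by["CASQ2"] == pytest.approx(0.75)

    def test_single_paralog_share_one(self):
        shares = compute_shares([expr("sp", "cardiac", "CASQ2", 42.0)])
        assert shares["share"].iloc[0] == 1.0

    def test_zero_family_share_undefined_not_zero_over_zero(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 0.0),
            expr("sp", "skeletal", "CASQ2", 0.0),
        ])
        assert shares["share"].isna().all()
        assert (shares["family_cpm"] == 0).all()

    def test_samples_mean_aggregated(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 100.0, "s1"),
            expr("sp", "skeletal", "CASQ1", 300.0, "s2"),
            expr("sp", "skeletal", "CASQ2", 200.0, "s1"),
        ])
        by = shares.set_index("paralog")["mean_cpm"]
        assert by["CASQ1"] == pytest.approx(200.0)

    def test_shares_sum_to_one_on_generated_data(self, default_scenario):
        shares = compute_shares(list(default_scenario.expression))
        sums = shares.groupby(["species", "tissue"])["share"].sum()
        assert np.all(np.abs(sums.to_numpy() - 1.0) <= 1e-9)


class TestCallDominance:
    def test_clear_majority_called(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 3960.0),
            expr("sp", "skeletal", "CASQ2", 40.0),
        ])
        (state,) = call_dominance(shares)
        assert state.state == "CASQ1"
        assert state.share == pytest.approx(0.99)

    def test_even_split_ambiguous(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 500.0),
            expr("sp", "skeletal", "CASQ2", 500.0),
        ])
        (state,) = call_dominance(shares)
        assert state.state == AMBIGUOUS

    def test_below_floor_ambiguous(self):
        shares = compute_shares([
            expr("sp", "skeletal", "CASQ1", 1.8),
            expr("sp", "skeletal", "CASQ2", 0.2),
        ])
        (state,) = call_dominance(shares, floor_cpm=10.0)
        assert state.state == AMBIGUOUS

    def test_missing_tissue_reported_no_data(self):
        shares = compute_shares([expr("sp1", "skeletal", "CASQ1", 100.0)])
        states = call_dominance(
            shares, species_universe=["sp1", "sp2"],
            tissues=["skeletal", "cardiac"],
        )
        by = {(s.species, s.tissue): s.state for s in states}
        assert by[("sp1", "skeletal")] == "CASQ1"
        assert by[("sp2", "cardiac")] == NO_DATA


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

class TestFitchMinChanges:
    def test_uniform_states_zero_changes(self):
        tree = Cladogram.from_newick("((a,b),(c,d));")
        count, _ = fitch_min_changes(tree, {s: "A" for s in "abcd"})
        assert count == 0

    def test_single_clade_flip_costs_one(self):
        tree = Cladogram.from_newick(
            "(((a,b),(c,(d,e))),((f,g),h));"
        )
        states = {s: "A" for s in "abcdefgh"}
        for s in ("c", "d", "e"):
            states[s] = "B"
        count, _ = fitch_min_changes(tree, states)
        assert count == 1
        assert count == brute_force_min_changes(tree, states)

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 8))
            tree = random_tree(n, rng)
            states = {
                f"t{i}": ("A", "B")[int(rng.integers(2))] for i in range(n)
            }
            count, _ = fitch_min_changes(tree, states)
            assert count == brute_force_min_changes(tree, states)

    def test_no_data_leaves_pruned(self):
        tree = Cladogram.from_newick("((a,b),(c,d));")
        count, _ = fitch_min_changes(tree, {"a": "A", "b": "A", "c": "B"})
        assert count == 1

    def test_empty_states_rejected(self):
        tree = Cladogram.from_newick("((a,b),c);")
        with pytest.raises(ValueError):
            fitch_min_changes(tree, {})


# ---------------------------------------------------------------------------
# shift events
# ---------------------------------------------------------------------------

def dominance_from_states(states: dict[str, str], tissue="skeletal"):
    return [
        DominanceState(sp, tissue, st, 0.9, 1000.0) for sp, st in states.items()
    ]


class TestDetectShiftEvents:
    def test_no_variation_no_events(self):
        tree = Cladogram.from_newick("((a,b),(c,d));")
        dom = dominance_from_states({s: "CASQ1" for s in "abcd"})
        assert detect_shift_events(dom, tree, "skeletal") == []

    def test_single_clade_flip_one_unambiguous_event(self):
        tree = Cladogram.from_newick("(((a,b),(c,(d,e))),((f,g),h));")
        states = {s: "A" for s in "abcdefgh"}
        for s in ("c", "d", "e"):
            states[s] = "B"
        dom = dominance_from_states(states)
        events = detect_shift_events(dom, tree, "skeletal")
        unamb = [e for e in events if e.unambiguous]
        assert len(unamb) == 1
        assert unamb[0].clade_leaves == frozenset("cde")
        assert unamb[0].from_state == "A"
        assert unamb[0].to_state == "B"

    def test_matches_exhaustive_mpr_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            tree = random_tree(n, rng)
            states = {
                f"t{i}": ("A", "B")[int(rng.integers(2))] for i in range(n)
            }
            if len(set(states.values())) < 2:
                continue
            dom = dominance_from_states(states)
            events = detect_shift_events(dom, tree, "skeletal")
            oracle = brute_force_edge_changes(tree, states)
            got = {e.branch: e.unambiguous for e in events}
            expected = {
                br: always for br, (some, always) in oracle.items() if some
            }
            assert got == expected

    def test_leaf_order_invariance(self):
        t1 = Cladogram.from_newick("((a,b),(c,d));")
        t2 = Cladogram.from_newick("((d,c),(b,a));")
        states = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        dom = dominance_from_states(states)
        e1 = detect_shift_events(dom, t1, "skeletal")
        e2 = detect_shift_events(dom, t2, "skeletal")
        assert {frozenset(e.clade_leaves) for e in e1} == {
            frozenset(e.clade_leaves) for e in e2
        }

    def test_count_scale_invariance(self):
        """Shares are scale-free: multiplying all counts by a constant
        changes no dominance state and no event."""
        config = ScenarioConfig(seed=3)
        tree = simulate_tree(config)
        records, _ = simulate_expression(tree, config)
        scaled = [
            ExpressionRecord(
                r.species, r.tissue, r.paralog, r.sample_id,
                est_counts=r.est_counts * 7, total_mapped=r.total_mapped * 7,
            )
            for r in records
        ]
        for recs in (records, scaled):
            dom = call_dominance(compute_shares(recs))
            events = detect_shift_events(dom, tree, "skeletal")
            assert [e.branch for e in events] == [
                tree.node_label(tree.mrca(config.focal_species))
            ]

    def test_ambiguous_and_no_data_leaves_carry_no_signal(self):
        tree = Cladogram.from_newick("((a,b),(c,(d,e)));")
        dom = dominance_from_states(
            {"a": "X", "b": "X", "c": AMBIGUOUS, "d": NO_DATA, "e": "Y"}
        )
        events = detect_shift_events(dom, tree, "skeletal")
        assert len(events) > 0
        for e in events:
            assert AMBIGUOUS not in (e.from_state, e.to_state)

    def test_all_unusable_states_warns_and_returns_empty(self):
        tree = Cladogram.from_newick("((a,b),c);")
        dom = dominance_from_states({"a": AMBIGUOUS, "b": NO_DATA})
        with pytest.warns(UserWarning):
            assert detect_shift_events(dom, tree, "skeletal") == []


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def build_report(data):
    shares = compute_shares(list(data.expression))
    dom = call_dominance(
        shares, species_universe=data.tree.leaf_names,
        tissues=list(data.config.tissues),
    )
    sk = detect_shift_events(dom, data.tree, "skeletal")
    ca = detect_shift_events(dom, data.tree, "cardiac")
    status = status_matrix(
        [classify_gene_status(m, ref_exon_count=data.config.ref_exon_count)
         for m in data.exon_maps],
        data.tree,
    )
    summaries = region_charge_summaries(data.alignment, data.region_map)
    grouping = {
        r.id: r.clade for r in data.alignment
        if r.paralog == data.config.tail_boost_paralog
    }
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comps = {
            reg: compare_groups(summaries, grouping, reg)
            for reg in ("domains", "cterm")
        }
    return synfunctionalization_report(
        sk, ca, status, comps, data.tree, data.truth.species_clades,
        shares=shares,
    ), sk, ca


class TestSynfunctionalizationReport:
    def test_full_scenario_names_planted_branch(self, default_scenario):
        report, sk, ca = build_report(default_scenario)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["branch"] == default_scenario.truth.flip_branch
        assert row["tissue"] == "skeletal"
        assert row["unambiguous"]
        assert row["n_displaced_pseudogenized"] == len(
            default_scenario.truth.pseudogenized
        )
        assert row["cterm_tier"] == "***"
        assert row["domains_tier"] == "ns"
        assert ca == []

    def test_null_scenario_empty_report(self):
        config = ScenarioConfig(seed=5, flip=None, exon_deletion=None,
                                tail_boost=0.0)
        data = simulate_scenario(config)
        report, sk, ca = build_report(data)
        assert report.empty
        assert sk == [] and ca == []

    def test_shift_without_decay_is_reported_as_such(self):
        config = ScenarioConfig(seed=7, exon_deletion=None)
        data = simulate_scenario(config)
        report, _, _ = build_report(data)
        assert len(report) == 1
        assert report.iloc[0]["decay"] == "no decay observed"
        assert report.iloc[0]["n_displaced_pseudogenized"] == 0

    def test_events_frame_columns(self, default_scenario):
        _, sk, _ = build_report(default_scenario)
        df = events_to_frame(sk)
        assert list(df["branch"]) == [default_scenario.truth.flip_branch]
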