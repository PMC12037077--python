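"""Synthetic-scenario generator for the whole pipeline.

Generates every pipeline input with the statistical structure the analysis
assumes — clade-structured sequences for two diverged paralog families, per
species x tissue x sample expression tables, exon presence maps, and a
species cladogram — together with the ground truth planted into them, so
every stage can be tested end to end without external data.

The shipped default scenario emulates the avian calsequestrin pattern:

* 12 "non-focal" species in three monophyletic clades plus a 6-species
  focal clade nested among them;
* two paralog families (CASQ1 / CASQ2) diverged at 30% of columns, with
  small within-family substitution along the tree;
* an acidity boost of the focal clade's CASQ2 C-terminal tail, applied once
  on the focal stem (a single ancestral event inherited by the clade);
* CASQ1 dominating skeletal muscle and CASQ2 dominating cardiac muscle
  everywhere, except that skeletal dominance flips to CASQ2 on the focal
  stem (with the focal clade's skeletal CASQ2 elevated relative to its
  cardiac CASQ2);
* deletion of exons 2 and 3 of CASQ1 in a 3-species focal subclade.

Expression noise is log-normal on the cpm scale (scale 0.3 by default), a
deliberate modeling choice matching typical gene-level bulk RNA-seq
dispersion.  Sequence evolution is i.i.d. per-column substitution along the
tree with no rate matrix — deliberately simple, sufficient for distance /
charge / classification testing.  All output is deterministic given the
config (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    AMINO_ACIDS,
    AlignedSequenceSet,
    Cladogram,
    EXON_MISSING,
    EXON_PRESENT,
    ExonMap,
    ExpressionRecord,
    RegionMap,
    SequenceRecord,
    write_exon_tsv,
    write_expression_tsv,
    write_fasta,
    write_newick,
    write_region_config,
)

_N_AA = len(AMINO_ACIDS)
_ASP = AMINO_ACIDS.index("D")
_GLU = AMINO_ACIDS.index("E")
#: expected charge of a uniformly random residue (3 positive, 2 negative of 20)
_MEAN_RANDOM_CHARGE = (3 - 2) / _N_AA


@dataclass(frozen=True)
class FlipSpec:
    """A planted dominance flip: below the focal stem, ``tissue``'s dominant
    paralog becomes ``to_paralog`` instead of the ancestral one."""

    tissue: str = "skeletal"
    to_paralog: str = "CASQ2"


@dataclass(frozen=True)
class ExonDeletionSpec:
    """Planted exon deletions in a subclade of the focal clade."""

    paralog: str = "CASQ1"
    exons: tuple[int, ...] = (2, 3)   # 1-based exon numbers
    n_species: int = 3                # leading focal subclade size


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic scenario.

    Defaults are the shipped study conditions (see module docstring).
    """

    seed: int = 0
    n_focal: int = 6
    focal_clade: str = "AVES"
    nonfocal_clades: tuple[str, ...] = ("MAM", "SQU", "CRO")
    n_per_nonfocal_clade: int = 4
    fixed_topology: str | None = None

    # alignment
    aln_length: int = 300
    domains_region: tuple[int, int] = (20, 260)
    cterm_region: tuple[int, int] = (270, 300)
    paralogs: tuple[str, str] = ("CASQ1", "CASQ2")
    inter_paralog_divergence: float = 0.30
    subst_rate: float = 0.004          # per column per tree edge
    tail_boost: float = 0.30           # P(column -> D/E) on focal stem
    tail_boost_paralog: str = "CASQ2"

    # expression
    tissues: tuple[str, str] = ("skeletal", "cardiac")
    skeletal_dominant: str = "CASQ1"
    cardiac_dominant: str = "CASQ2"
    dominant_cpm: float = 900.0
    minor_cpm: float = 100.0
    lognormal_sigma: float = 0.3
    samples_per_tissue: int = 2
    total_mapped: float = 2.0e7
    focal_skeletal_scale: float = 2.5  # flipped skeletal dominant vs cardiac
    flip: FlipSpec | None = field(default_factory=FlipSpec)

    # exon maps
    ref_exon_count: int = 11
    exon_deletion: ExonDeletionSpec | None = field(
        default_factory=ExonDeletionSpec
    )

    def __post_init__(self) -> None:
        for p, name in ((self.inter_paralog_divergence, "inter_paralog_divergence"),
                        (self.subst_rate, "subst_rate"),
                        (self.tail_boost, "tail_boost")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_focal < 2 or self.n_per_nonfocal_clade < 2:
            raise ValueError("need at least 2 species per clade")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")
        d0, d1 = self.domains_region
        c0, c1 = self.cterm_region
        if not (0 <= d0 < d1 <= self.aln_length and 0 <= c0 < c1 <= self.aln_length):
            raise ValueError("region layout inconsistent with alignment length")
        if self.exon_deletion is not None:
            bad = [e for e in self.exon_deletion.exons
                   if not 1 <= e <= self.ref_exon_count]
            if bad:
                raise ValueError(f"exon indices out of range: {bad}")
            if self.exon_deletion.n_species > self.n_focal:
                raise ValueError("exon-deletion subclade larger than focal clade")

    # -- derived ----------------------------------------------------------
    @property
    def focal_species(self) -> list[str]:
        return [f"{self.focal_clade.lower()}_{i + 1}" for i in range(self.n_focal)]

    @property
    def nonfocal_species(self) -> dict[str, list[str]]:
        return {
            clade: [
                f"{clade.lower()}_{i + 1}"
                for i in range(self.n_per_nonfocal_clade)
            ]
            for clade in self.nonfocal_clades
        }

    @property
    def species_clades(self) -> dict[str, str]:
        out = {sp: self.focal_clade for sp in self.focal_species}
        for clade, spp in self.nonfocal_species.items():
            out.update({sp: clade for sp in spp})
        return out

    @property
    def region_map(self) -> RegionMap:
        return RegionMap(
            regions={
                "whole": (0, self.aln_length),
                "domains": self.domains_region,
                "cterm": self.cterm_region,
            },
            n_columns=self.aln_length,
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery checks."""

    species_clades: dict[str, str]
    paralog_of: dict[str, str]             # sequence id -> true paralog
    flip_clade: frozenset[str] | None      # leaves below the planted branch
    flip_branch: str | None                # branch label on the tree
    flip_tissue: str | None
    pseudogenized: frozenset[tuple[str, str]]  # (species, paralog)
    expected_cterm_offset: float


@dataclass(frozen=True)
class ScenarioData:
    config: ScenarioConfig
    tree: Cladogram
    alignment: AlignedSequenceSet
    region_map: RegionMap
    expression: tuple[ExpressionRecord, ...]
    exon_maps: tuple[ExonMap, ...]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _bisect(items: list, rng: np.random.Generator):
    """Random rooted binary topology over ``items`` by recursive bisection."""
    if len(items) == 1:
        return items[0]
    order = rng.permutation(len(items))
    k = int(rng.integers(1, len(items)))
    left = [items[i] for i in order[:k]]
    right = [items[i] for i in order[k:]]
    return (_bisect(left, rng), _bisect(right, rng))


def _paths(t, prefix=()):
    yield prefix
    if isinstance(t, tuple):
        for i, c in enumerate(t):
            yield from _paths(c, prefix + (i,))


def _replace(t, path, new):
    if not path:
        return new
    return tuple(
        _replace(c, path[1:], new) if j == path[0] else c for j, c in enumerate(t)
    )


def _to_newick(t) -> str:
    if isinstance(t, tuple):
        return "(" + ",".join(_to_newick(c) for c in t) + ")"
    return str(t)


def simulate_tree(config: ScenarioConfig) -> Cladogram:
    """Rooted binary species cladogram, deterministic given the config seed.

    Non-focal clades are monophyletic subtrees; the focal clade is grafted
    onto a random non-root branch so its stem is always an internal branch
    (a one-change reconstruction on that stem is then unique).  The leading
    ``exon_deletion.n_species`` focal species always form a subclade.
    ``fixed_topology`` (Newick) overrides everything.
    """
    if config.fixed_topology is not None:
        return Cladogram.from_newick(config.fixed_topology)
    rng = config.rng(stream=1)
    clade_subtrees = [
        _bisect(list(spp), rng) for spp in config.nonfocal_species.values()
    ]
    backbone = _bisect(clade_subtrees, rng)
    # focal subtree: leading subclade kept monophyletic
    n_sub = config.exon_deletion.n_species if config.exon_deletion else 2
    focal = config.focal_species
    head = _bisect(focal[:n_sub], rng)
    tail = _bisect(focal[n_sub:], rng) if focal[n_sub:] else None
    focal_tree = (head, tail) if tail is not None else head
    # graft on a random non-root branch of the backbone
    candidates = [p for p in _paths(backbone) if p != ()]
    path = candidates[int(rng.integers(len(candidates)))]
    grafted = _replace(backbone, path, (_subtree_at(backbone, path), focal_tree))
    return Cladogram.from_newick(_to_newick(grafted) + ";")


def _subtree_at(t, path):
    for i in path:
        t = t[i]
    return t


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        # shift by 1..19 guarantees a different residue
        out[hit] = (out[hit] + rng.integers(1, _N_AA, n)) % _N_AA
    return out


def _boost_tail(
    seq: np.ndarray, cterm: tuple[int, int], boost: float, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    c0, c1 = cterm
    hit = rng.random(c1 - c0) < boost
    acidic = np.where(rng.random(c1 - c0) < 0.9, _ASP, _GLU)
    window = out[c0:c1]
    window[hit] = acidic[hit]
    out[c0:c1] = window
    return out


def seq_id(species: str, paralog: str) -> str:
    return f"{species}_{paralog}"


def simulate_alignment(
    tree: Cladogram, config: ScenarioConfig
) -> tuple[AlignedSequenceSet, dict[str, str]]:
    """Two paralog families evolved along the tree.

    The two family ancestors differ at ``inter_paralog_divergence`` of
    columns; each family then evolves down the tree by i.i.d. per-column
    substitution at ``subst_rate`` per branch.  On the focal stem the
    ``tail_boost_paralog`` ancestor has each C-terminal column replaced by
    D (90%) or E (10%) with probability ``tail_boost``.  Returns the
    alignment and the id -> true-paralog map.
    """
    rng = config.rng(stream=2)
    L = config.aln_length
    anc_a = rng.integers(0, _N_AA, L)
    div = rng.random(L) < config.inter_paralog_divergence
    anc_b = anc_a.copy()
    n_div = int(div.sum())
    anc_b[div] = (anc_b[div] + rng.integers(1, _N_AA, n_div)) % _N_AA

    focal_mrca = tree.mrca(config.focal_species)
    clades = config.species_clades
    records: list[SequenceRecord] = []
    paralog_of: dict[str, str] = {}
    for paralog, anc in zip(config.paralogs, (anc_a, anc_b)):
        seqs: dict[int, np.ndarray] = {}
        for nd in tree.preorder():
            if nd.parent_node is None:
                s = anc.copy()
            else:
                s = _mutate(seqs[id(nd.parent_node)], config.subst_rate, rng)
            if nd is focal_mrca and paralog == config.tail_boost_paralog:
                s = _boost_tail(s, config.cterm_region, config.tail_boost, rng)
            seqs[id(nd)] = s
            if nd.is_leaf():
                sp = nd.taxon.label
                sid = seq_id(sp, paralog)
                residues = "".join(AMINO_ACIDS[i] for i in s)
                records.append(
                    SequenceRecord(
                        id=sid, species=sp, clade=clades[sp],
                        paralog=paralog, residues=residues,
                    )
                )
                paralog_of[sid] = paralog
    records.sort(key=lambda r: r.id)
    return AlignedSequenceSet(tuple(records)), paralog_of


def expected_cterm_offset(config: ScenarioConfig) -> float:
    """Closed-form expected focal-minus-others c-terminal net-charge offset
    under the generative model (boosted columns go from a uniformly random
    residue, mean charge +1/20, to charge -1)."""
    c0, c1 = config.cterm_region
    return -config.tail_boost * (c1 - c0) * (1.0 + _MEAN_RANDOM_CHARGE)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _dominant_paralog(
    config: ScenarioConfig, species: str, tissue: str, flipped: frozenset[str]
) -> str:
    if (
        config.flip is not None
        and tissue == config.flip.tissue
        and species in flipped
    ):
        return config.flip.to_paralog
    return (
        config.skeletal_dominant if tissue == "skeletal" else config.cardiac_dominant
    )


def simulate_expression(
    tree: Cladogram, config: ScenarioConfig
) -> tuple[list[ExpressionRecord], frozenset[str]]:
    """Per species x tissue x paralog x sample expression records.

    cpm is log-normal around the dominant/minor location for the species x
    tissue (the planted flip redirects dominance below the focal stem in the
    flipped tissue only); counts are ``round(cpm * total_mapped / 1e6)``.
    Returns the records and the flipped leaf set (empty if no flip).
    """
    rng = config.rng(stream=3)
    flipped = (
        frozenset(config.focal_species) if config.flip is not None else frozenset()
    )
    records: list[ExpressionRecord] = []
    for species in sorted(config.species_clades):
        for tissue in config.tissues:
            dom = _dominant_paralog(config, species, tissue, flipped)
            for paralog in config.paralogs:
                loc = config.dominant_cpm if paralog == dom else config.minor_cpm
                if (
                    species in flipped
                    and config.flip is not None
                    and tissue == config.flip.tissue
                    and paralog == dom
                ):
                    loc *= config.focal_skeletal_scale
                for k in range(config.samples_per_tissue):
                    cpm = rng.lognormal(math.log(loc), config.lognormal_sigma)
                    est = round(cpm * config.total_mapped / 1e6)
                    records.append(
                        ExpressionRecord(
                            species=species, tissue=tissue, paralog=paralog,
                            sample_id=f"{species}_{tissue}_s{k + 1}",
                            est_counts=float(est),
                            total_mapped=float(config.total_mapped),
                        )
                    )
    return records, flipped


# ---------------------------------------------------------------------------
# exon maps
# ---------------------------------------------------------------------------

def simulate_exon_maps(
    tree: Cladogram, config: ScenarioConfig
) -> tuple[list[ExonMap], frozenset[tuple[str, str]]]:
    """All-present exon maps except the planted subclade deletions.

    Returns the maps plus the planted (species, paralog) pseudogenization
    set.
    """
    deletion = config.exon_deletion
    del_species = (
        frozenset(config.focal_species[: deletion.n_species])
        if deletion is not None
        else frozenset()
    )
    maps: list[ExonMap] = []
    planted: set[tuple[str, str]] = set()
    for species in sorted(config.species_clades):
        for paralog in config.paralogs:
            status = [EXON_PRESENT] * config.ref_exon_count
            if (
                deletion is not None
                and paralog == deletion.paralog
                and species in del_species
            ):
                for e in deletion.exons:
                    status[e - 1] = EXON_MISSING
                planted.add((species, paralog))
            maps.append(
                ExonMap(species=species, paralog=paralog, exon_status=tuple(status))
            )
    return maps, frozenset(planted)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig | None = None) -> ScenarioData:
    """Generate the complete scenario bundle from one config."""
    if config is None:
        config = ScenarioConfig()
    tree = simulate_tree(config)
    missing = set(config.species_clades) - set(tree.leaf_names)
    if missing:
        raise ValueError(f"tree lacks configured species: {sorted(missing)}")
    alignment, paralog_of = simulate_alignment(tree, config)
    expression, flipped = simulate_expression(tree, config)
    exon_maps, planted = simulate_exon_maps(tree, config)
    flip_branch = None
    if flipped:
        flip_branch = tree.node_label(tree.mrca(flipped))
    truth = GroundTruth(
        species_clades=config.species_clades,
        paralog_of=paralog_of,
        flip_clade=flipped or None,
        flip_branch=flip_branch,
        flip_tissue=config.flip.tissue if config.flip else None,
        pseudogenized=planted,
        expected_cterm_offset=expected_cterm_offset(config),
    )
    return ScenarioData(
        config=config, tree=tree, alignment=alignment,
        region_map=config.region_map,
        expression=tuple(expression), exon_maps=tuple(exon_maps), truth=truth,
    )


def write_scenario(data: ScenarioData, outdir: str | Path) -> None:
    """Write every pipeline input (plus ground truth and config) as text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.alignment, outdir / "alignment.fasta")
    write_newick(data.tree, outdir / "tree.nwk")
    write_expression_tsv(list(data.expression), outdir / "expression.tsv")
    write_exon_tsv(list(data.exon_maps), outdir / "exons.tsv")
    write_region_config(data.region_map, outdir / "regions.yaml")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(data.config), fh, sort_keys=False)
    truth = data.truth
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"flip_branch\t{truth.flip_branch or ''}\n")
        fh.write(f"flip_tissue\t{truth.flip_tissue or ''}\n")
        fh.write(
            "flip_clade\t"
            + ",".join(sorted(truth.flip_clade or frozenset()))
            + "\n"
        )
        fh.write(
            "pseudogenized\t"
            + ",".join(sorted(f"{s}:{p}" for s, p in truth.pseudogenized))
            + "\n"
        )
        fh.write(f"expected_cterm_offset\t{truth.expected_cterm_offset}\n")
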