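"""Core domain types and file I/O.

Every downstream module consumes only the types defined here: gapped protein
alignments with species/clade/paralog metadata, rooted species cladograms,
per-sample expression records, exon presence maps, and named alignment-column
regions.  Readers are thin validating wrappers over Bio.SeqIO (FASTA),
dendropy (Newick), pandas (TSV) and PyYAML (region config).

Conventions
-----------
* FASTA headers encode metadata as ``id|species|clade|paralog`` (pipe
  delimited; the paralog field may be empty).
* Alignment coordinates are 0-based half-open internally; human-facing
  reports (e.g. missing exon lists) are 1-based inclusive.
* Expression tables carry counts-per-million computed as
  ``cpm = est_counts / total_mapped * 1e6``.  TPM columns, if present, are
  passed through untouched but never computed here (that would require
  effective transcript lengths, which this model does not track).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted in alignments: amino acids, unknown, gap
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X-")
GAP = "-"

HEADER_DELIMITER = "|"

#: exon states accepted in exon maps (TSV codes P / M / X)
EXON_PRESENT = "present"
EXON_MODIFIED = "modified"
EXON_MISSING = "missing"
EXON_STATES = (EXON_PRESENT, EXON_MODIFIED, EXON_MISSING)
_EXON_CODE = {"P": EXON_PRESENT, "M": EXON_MODIFIED, "X": EXON_MISSING}
_EXON_CODE_INV = {v: k for k, v in _EXON_CODE.items()}

#: default number of reference exons in the gene family
DEFAULT_REF_EXON_COUNT = 11


class ParseError(ValueError):
    """A record could not be parsed (malformed header, bad value)."""


class AlignmentError(ValueError):
    """Sequences that must be aligned have inconsistent lengths."""


class SchemaError(ValueError):
    """A table is missing required columns or has malformed fields."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One gapped protein sequence with its taxonomic/paralog metadata."""

    id: str
    species: str
    clade: str
    residues: str
    paralog: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence id must be non-empty")
        if not self.residues:
            raise ParseError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ParseError(
                f"record {self.id!r}: disallowed residue characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def header(self) -> str:
        return HEADER_DELIMITER.join(
            [self.id, self.species, self.clade, self.paralog or ""]
        )


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A multiple sequence alignment: records of identical length."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if not recs:
            raise AlignmentError("alignment must contain at least one record")
        n = len(recs[0].residues)
        for r in recs:
            if len(r.residues) != n:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate sequence ids: {dupes}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        wanted = set(ids)
        return AlignedSequenceSet(tuple(r for r in self.records if r.id in wanted))

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _record_from_header(header: str, residues: str) -> SequenceRecord:
    parts = header.split(HEADER_DELIMITER)
    if len(parts) < 3:
        raise ParseError(
            f"malformed FASTA header {header!r}: expected "
            f"'id{HEADER_DELIMITER}species{HEADER_DELIMITER}clade"
            f"{HEADER_DELIMITER}paralog'"
        )
    seq_id, species, clade = parts[0], parts[1], parts[2]
    paralog = parts[3] if len(parts) > 3 and parts[3] else None
    return SequenceRecord(
        id=seq_id, species=species, clade=clade, paralog=paralog, residues=residues
    )


def read_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read a gapped FASTA alignment with ``id|species|clade|paralog`` headers."""
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description if rec.description else rec.id
            records.append(_record_from_header(header, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(tuple(records))


def write_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write the alignment as FASTA, wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.header(), description="")
        for r in aln.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

REQUIRED_REGIONS = ("whole", "domains", "cterm")


@dataclass(frozen=True)
class RegionMap:
    """Named alignment-column intervals, 0-based half-open.

    Required names: ``whole`` (all columns), ``domains`` (structural
    domains), ``cterm`` (C-terminal tail).  ``domains`` and ``cterm`` must
    not overlap.
    """

    regions: Mapping[str, tuple[int, int]]
    n_columns: int

    def __post_init__(self) -> None:
        regions = {k: (int(a), int(b)) for k, (a, b) in dict(self.regions).items()}
        object.__setattr__(self, "regions", regions)
        for name in REQUIRED_REGIONS:
            if name not in regions:
                raise SchemaError(f"region map missing required region {name!r}")
        for name, (a, b) in regions.items():
            if not (0 <= a < b <= self.n_columns):
                raise SchemaError(
                    f"region {name!r} interval [{a}, {b}) outside "
                    f"[0, {self.n_columns})"
                )
        if regions["whole"] != (0, self.n_columns):
            raise SchemaError("region 'whole' must span all alignment columns")
        d0, d1 = regions["domains"]
        c0, c1 = regions["cterm"]
        if max(d0, c0) < min(d1, c1):
            raise SchemaError("'domains' and 'cterm' regions overlap")

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.regions[name]

    def names(self) -> list[str]:
        return list(self.regions)


def read_region_config(path: str | Path) -> RegionMap:
    """Read a YAML region config: ``n_columns`` plus ``regions: {name: [a, b]}``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        n_columns = int(cfg["n_columns"])
        regions = {str(k): (int(v[0]), int(v[1])) for k, v in cfg["regions"].items()}
    except (KeyError, TypeError, IndexError) as exc:
        raise SchemaError(f"malformed region config {path}: {exc}") from exc
    return RegionMap(regions=regions, n_columns=n_columns)


def write_region_config(region_map: RegionMap, path: str | Path) -> None:
    cfg = {
        "n_columns": region_map.n_columns,
        "regions": {k: list(v) for k, v in region_map.regions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class Cladogram:
    """A rooted species cladogram (topology only) wrapping a dendropy tree.

    Internal nodes receive stable, unique labels (existing labels are kept;
    unlabeled nodes get ``N1``, ``N2``, ... in postorder) so that branches can
    be referred to by their child-node label.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ParseError(f"duplicate leaf names in tree: {dupes}")
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            logger.warning(
                "tree root has %d children (trifurcating / unrooted-style root "
                "accepted as-is)", len(root.child_nodes()),
            )
        self._label_internal_nodes()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Cladogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ParseError(f"duplicate leaf names in tree: {exc}") from exc
        return cls(tree)

    def _label_internal_nodes(self) -> None:
        used = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf() and nd.label:
                used.add(nd.label)
        counter = 1
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf() or nd.label:
                continue
            while f"N{counter}" in used:
                counter += 1
            nd.label = f"N{counter}"
            used.add(nd.label)

    # -- queries ----------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def clade_leaves(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def find_node(self, label: str) -> dendropy.Node:
        for nd in self.tree.preorder_node_iter():
            if self.node_label(nd) == label:
                return nd
        raise KeyError(f"no node labeled {label!r}")

    def mrca(self, leaf_labels: Iterable[str]) -> dendropy.Node:
        labels = list(leaf_labels)
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise KeyError(f"no MRCA for {labels}")
        return node

    def postorder(self):
        return self.tree.postorder_node_iter()

    def preorder(self):
        return self.tree.preorder_node_iter()

    # -- transforms -------------------------------------------------------
    def pruned_to(self, leaf_labels: Iterable[str]) -> "Cladogram":
        """Return a new cladogram restricted to the given leaves
        (unifurcations suppressed)."""
        keep = set(leaf_labels)
        missing = keep - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not on tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True,
        )
        return Cladogram(sub)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, suppress_edge_lengths=True,
            unquoted_underscores=True,
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Cladogram({len(self.leaf_names)} leaves)"


def read_newick(path: str | Path) -> Cladogram:
    """Read a rooted Newick tree; leaf names must be unique."""
    with open(path) as fh:
        return Cladogram.from_newick(fh.read())


def write_newick(tree: Cladogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

CPM_SCALE = 1e6

EXPRESSION_COLUMNS = (
    "species", "tissue", "paralog", "sample_id", "est_counts", "total_mapped", "cpm",
)


@dataclass(frozen=True)
class ExpressionRecord:
    """One paralog quantification in one RNA-seq sample.

    ``cpm`` is derived (``est_counts / total_mapped * 1e6``) when both counts
    are available; a record may instead carry a precomputed ``cpm`` with
    ``total_mapped`` unknown (pass-through contract).
    """

    species: str
    tissue: str
    paralog: str
    sample_id: str
    est_counts: float | None = None
    total_mapped: float | None = None
    cpm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        est, tot, cpm = self.est_counts, self.total_mapped, self.cpm
        if est is not None and est < 0:
            raise ValueError(f"negative est_counts for {self.species}/{self.paralog}")
        if tot is not None and tot <= 0:
            raise ValueError(f"non-positive total_mapped for {self.species}")
        if est is not None and tot is not None:
            if est > tot:
                raise ValueError(
                    f"est_counts {est} exceeds total_mapped {tot} "
                    f"({self.species}/{self.tissue}/{self.paralog})"
                )
            object.__setattr__(self, "cpm", est / tot * CPM_SCALE)
        elif cpm is None:
            raise ValueError(
                f"record {self.species}/{self.tissue}/{self.paralog}: "
                "needs est_counts+total_mapped or cpm"
            )
        if self.cpm is not None and (self.cpm < 0 or not math.isfinite(self.cpm)):
            raise ValueError(f"invalid cpm {self.cpm}")


def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """Read a per-sample expression TSV.

    Requires columns ``species, tissue, paralog, sample_id`` plus either
    ``est_counts`` and ``total_mapped`` (cpm computed) or ``cpm``
    (pass-through).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"species", "tissue", "paralog", "sample_id"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    has_counts = {"est_counts", "total_mapped"} <= set(df.columns)
    if not has_counts and "cpm" not in df.columns:
        raise SchemaError(
            f"{path}: need est_counts+total_mapped columns or a cpm column"
        )

    def _num(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            ExpressionRecord(
                species=row["species"],
                tissue=row["tissue"],
                paralog=row["paralog"],
                sample_id=row["sample_id"],
                est_counts=_num(row, "est_counts"),
                total_mapped=_num(row, "total_mapped"),
                cpm=_num(row, "cpm"),
            )
        )
    return records


def write_expression_tsv(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = expression_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def expression_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "tissue": r.tissue,
                "paralog": r.paralog,
                "sample_id": r.sample_id,
                "est_counts": r.est_counts,
                "total_mapped": r.total_mapped,
                "cpm": r.cpm,
            }
            for r in records
        ],
        columns=list(EXPRESSION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# exon maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonMap:
    """Per-gene exon presence states relative to the reference exon layout."""

    species: str
    paralog: str
    exon_status: tuple[str, ...]

    def __post_init__(self) -> None:
        status = tuple(self.exon_status)
        object.__setattr__(self, "exon_status", status)
        if not status:
            raise SchemaError(f"{self.species}/{self.paralog}: empty exon map")
        bad = set(status) - set(EXON_STATES)
        if bad:
            raise SchemaError(
                f"{self.species}/{self.paralog}: invalid exon states {sorted(bad)}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exon_status)


def read_exon_tsv(path: str | Path) -> list[ExonMap]:
    """Read exon maps: columns ``species, paralog, exon_1..exon_N`` with
    one-letter codes P (present), M (modified), X (missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species", "paralog"} <= set(df.columns):
        raise SchemaError(f"{path}: missing species/paralog columns")
    exon_cols = sorted(
        (c for c in df.columns if c.startswith("exon_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not exon_cols:
        raise SchemaError(f"{path}: no exon_N columns")
    maps = []
    for _, row in df.iterrows():
        codes = [str(row[c]).strip().upper() for c in exon_cols]
        try:
            status = tuple(_EXON_CODE[c] for c in codes)
        except KeyError as exc:
            raise SchemaError(
                f"{path}: invalid exon code {exc} for {row['species']}"
            ) from exc
        maps.append(ExonMap(species=row["species"], paralog=row["paralog"],
                            exon_status=status))
    return maps


def write_exon_tsv(maps: Sequence[ExonMap], path: str | Path) -> None:
    if not maps:
        raise ValueError("no exon maps to write")
    n = maps[0].n_exons
    cols = ["species", "paralog"] + [f"exon_{i + 1}" for i in range(n)]
    rows = []
    for m in maps:
        if m.n_exons != n:
            raise SchemaError("inconsistent exon counts across maps")
        rows.append([m.species, m.paralog] + [_EXON_CODE_INV[s] for s in m.exon_status])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
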