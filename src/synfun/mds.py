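"""Simple amino-acid distance matrices and 2-D metric MDS.

Distances are plain mismatch counts over aligned columns (every difference
counts 1).  Gap handling is either ``pairwise-delete`` (columns with a gap in
either sequence are excluded from the comparison; the default) or
``count-as-mismatch`` (a gap opposite a residue counts as a difference;
columns gapped in both sequences are always excluded).

Note that pairwise-deleted mismatch counts are not guaranteed to form a
metric: the triangle inequality can fail when different pairs compare
different column sets.  Nothing here assumes metricity.

The embedding is 2-D metric MDS minimizing raw stress
``sum_{i<j} (d_ij - ||x_i - x_j||)^2`` by iterative stress majorization
(SMACOF / Guttman transform), initialized from classical scaling, with an
early stop on relative stress change.  Stress is non-increasing across
iterations by construction, and this is asserted on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .io import GAP, AlignedSequenceSet

GAP_MODES = ("pairwise-delete", "count-as-mismatch")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric mismatch-count matrix with per-pair compared-column counts.

    ``d`` holds NaN for pairs with zero compared columns (distance
    undefined).
    """

    ids: tuple[str, ...]
    d: np.ndarray           # float, shape (n, n)
    n_compared: np.ndarray  # int, shape (n, n)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValueError("matrix shapes inconsistent with ids")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def has_missing(self) -> bool:
        off_diag = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.d[off_diag]).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def pairwise_distances(
    aln: AlignedSequenceSet, gap_mode: str = "pairwise-delete"
) -> DistanceMatrix:
    """Mismatch-count distances between all sequence pairs of an alignment."""
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}")
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences for pairwise distances")
    seqs = np.array(
        [np.frombuffer(r.residues.encode("ascii"), dtype="S1") for r in aln.records]
    )
    gaps = seqs == GAP.encode()
    n = len(aln)
    d = np.zeros((n, n), dtype=float)
    n_comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = seqs[i] != seqs[i + 1:]
        if gap_mode == "pairwise-delete":
            comp = ~gaps[i] & ~gaps[i + 1:]
        else:  # count-as-mismatch: only both-gap columns are excluded
            comp = ~(gaps[i] & gaps[i + 1:])
        dist = (diff & comp).sum(axis=1)
        cnt = comp.sum(axis=1)
        d[i, i + 1:] = dist
        d[i + 1:, i] = dist
        n_comp[i, i + 1:] = cnt
        n_comp[i + 1:, i] = cnt
    np.fill_diagonal(n_comp, aln.n_columns)
    undefined = (n_comp == 0) & ~np.eye(n, dtype=bool)
    if undefined.any():
        warnings.warn(
            "some sequence pairs share zero compared columns; "
            "their distances are undefined (NaN)",
            stacklevel=2,
        )
        d[undefined] = np.nan
    return DistanceMatrix(ids=tuple(aln.ids()), d=d, n_compared=n_comp)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MdsEmbedding:
    ids: tuple[str, ...]
    coordinates: np.ndarray        # (n, 2)
    stress: float
    stress_sequence: np.ndarray    # stress after each majorization step
    iterations_run: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )


def _raw_stress(D: np.ndarray, X: np.ndarray) -> float:
    E = squareform(pdist(X))
    iu = np.triu_indices_from(D, k=1)
    return float(((D[iu] - E[iu]) ** 2).sum())


def _classical_scaling_init(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order[:2]], vecs[:, order[:2]]
    pos = np.clip(vals, 0.0, None)
    X = vecs * np.sqrt(pos)
    if np.any(pos <= 0) or np.linalg.matrix_rank(X) < min(2, n - 1):
        # degenerate: jitter with a seeded random start component
        X = X + rng.normal(scale=max(D.max(), 1.0) * 1e-3, size=(n, 2))
    return X


def _canonicalize(X: np.ndarray) -> np.ndarray:
    """Remove translation/rotation/reflection indeterminacy deterministically:
    center, rotate to principal axes, and fix each axis sign."""
    X = X - X.mean(axis=0)
    # principal-axis rotation
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for k in range(X.shape[1]):
        col = X[:, k]
        idx = np.argmax(np.abs(col))
        if col[idx] < 0:
            X[:, k] = -col
    return X


def mds_embed(
    dm: DistanceMatrix,
    max_iter: int = 10000,
    seed: int = 0,
    tol: float = 1e-9,
) -> MdsEmbedding:
    """Embed a complete distance matrix in 2-D by SMACOF stress majorization.

    ``max_iter`` is the optimizer's iteration budget; iteration stops early
    when the relative stress decrease falls below ``tol``.  Deterministic
    given ``seed`` (the seed only matters for degenerate matrices where the
    classical-scaling start is rank-deficient).  Output coordinates are
    canonicalized (centered, principal axes, fixed signs).
    """
    if dm.has_missing:
        raise ValueError(
            "distance matrix has undefined (NaN) pairs; impute or remove "
            "those sequences before embedding"
        )
    D = np.asarray(dm.d, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    X = _classical_scaling_init(D, rng)
    stress = _raw_stress(D, X)
    history = [stress]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        E = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(E > 0, D / E, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        new_stress = _raw_stress(D, X)
        if new_stress > stress * (1 + 1e-12) + 1e-12:
            raise AssertionError(
                f"stress increased during majorization: {stress} -> {new_stress}"
            )
        history.append(new_stress)
        converged = new_stress == 0.0 or (
            stress > 0
            and (stress - new_stress) / max(stress, np.finfo(float).tiny) < tol
        )
        stress = new_stress
        if converged:
            break
    return MdsEmbedding(
        ids=dm.ids,
        coordinates=_canonicalize(X),
        stress=float(stress),
        stress_sequence=np.asarray(history),
        iterations_run=iterations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cluster separation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeparationReport:
    """Silhouette score plus exact 2-D linear-separability of label groups."""

    silhouette: float
    separable: bool                       # all label pairs linearly separable
    pair_separable: dict[tuple[str, str], bool]


def _linearly_separable(a: np.ndarray, b: np.ndarray) -> bool:
    """Exact strict linear separability of two 2-D point sets via an LP
    feasibility problem: find w, b with w.x + b >= 1 on A and <= -1 on B."""
    n_a, n_b = a.shape[0], b.shape[0]
    # variables: w1, w2, b ; constraints A_ub x <= b_ub
    A_ub = np.vstack(
        [
            np.hstack([-a, -np.ones((n_a, 1))]),
            np.hstack([b, np.ones((n_b, 1))]),
        ]
    )
    b_ub = -np.ones(n_a + n_b)
    res = linprog(
        c=np.zeros(3), A_ub=A_ub, b_ub=b_ub,
        bounds=[(None, None)] * 3, method="highs",
    )
    return bool(res.status == 0)


def cluster_separation(
    embedding: MdsEmbedding, labels: Sequence[str]
) -> SeparationReport:
    """How well label groups separate in the 2-D embedding.

    Requires at least two distinct labels with at least two members each.
    The report is invariant to rigid motions of the embedding (silhouette
    uses distances; separability is affine-invariant).
    """
    labels = list(labels)
    if len(labels) != len(embedding.ids):
        raise ValueError("one label per embedded point required")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    counts = {u: labels.count(u) for u in uniq}
    small = [u for u, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"labels with <2 members: {small}")
    X = embedding.coordinates
    sil = float(silhouette_score(X, labels))
    pair_sep = {}
    arr = np.asarray(labels)
    for i, u in enumerate(uniq):
        for v in uniq[i + 1:]:
            pair_sep[(u, v)] = _linearly_separable(X[arr == u], X[arr == v])
    return SeparationReport(
        silhouette=sil,
        separable=all(pair_sep.values()),
        pair_separable=pair_sep,
    )
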