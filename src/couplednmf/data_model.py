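"""Domain containers and file I/O for coupled bipartite interaction networks.

Two bipartite networks (drug-disease and drug-target) are coupled through
the drugs they share ("anchor" drugs).  This module defines the containers
every other module consumes:

* :class:`BipartiteInteractionMatrix` -- sparse binary interaction matrix
  with string identifiers on both axes.
* :class:`SimilarityMatrix` -- symmetric non-negative intra-layer
  similarity (drug-drug, disease-disease or target-target), with its
  degree matrix and graph Laplacian via :func:`build_laplacian`.
* :class:`AnchorMap` -- the partial one-to-one drug mapping between the
  two domains, as index pairs and as a sparse 0/1 matrix.
* :class:`WeightMatrix` -- one-class confidence weights: 1 on observed
  interactions, ``w`` elsewhere.
* :class:`CrossDomainProblem` -- the full two-domain input bundle.

Files are plain text: edge lists (one interaction per line) and delimited
square similarity matrices with identifier headers.  Identifiers, never
integer indexes, appear on disk; all in-memory indexing is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BipartiteInteractionMatrix",
    "SimilarityMatrix",
    "LaplacianPair",
    "AnchorMap",
    "WeightMatrix",
    "DomainData",
    "CrossDomainProblem",
    "load_interactions",
    "write_interactions",
    "load_similarity",
    "write_similarity",
    "build_weight_matrix",
    "build_laplacian",
    "build_anchor_map",
    "write_anchor_map",
    "build_problem",
]

#: asymmetry below this is silently symmetrized; above it we warn first
SYM_SILENT_TOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BipartiteInteractionMatrix:
    """Sparse binary interaction matrix with identifier indexes.

    ``values[i, j] == 1`` means row entity ``row_ids[i]`` (a drug) interacts
    with column entity ``col_ids[j]`` (a disease or target); absent entries
    mean "unobserved", not "negative".
    """

    row_ids: list[str]
    col_ids: list[str]
    values: sp.csr_matrix
    domain_tag: str = "drug_disease"

    def __post_init__(self):
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column identifiers")
        if len(self.row_ids) == 0 or len(self.col_ids) == 0:
            raise ValueError("empty identifier list")
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        self.values.eliminate_zeros()
        if self.values.nnz and not np.all(self.values.data == 1.0):
            raise ValueError("interaction entries must be exactly 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_interactions(self) -> int:
        return int(self.values.nnz)

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def positive_pairs(self) -> np.ndarray:
        """Observed (row, col) index pairs, in deterministic CSR order."""
        coo = self.values.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def with_values(self, values: sp.spmatrix) -> "BipartiteInteractionMatrix":
        return BipartiteInteractionMatrix(
            list(self.row_ids), list(self.col_ids), sp.csr_matrix(values),
            self.domain_tag,
        )


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative intra-layer similarity matrix."""

    ids: list[str]
    values: np.ndarray
    scale_note: str = "bounded_01"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers in similarity matrix")
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("similarity entries must be non-negative")
        asym = np.max(np.abs(self.values - self.values.T), initial=0.0)
        if asym > SYM_SILENT_TOL:
            warnings.warn(
                f"similarity matrix asymmetric (max deviation {asym:.3g}); "
                "symmetrizing as (A + A^T)/2"
            )
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class LaplacianPair:
    """Diagonal degree matrix D (stored as its diagonal) and L = D - A."""

    degree: np.ndarray
    laplacian: np.ndarray


@dataclass
class AnchorMap:
    """Partial one-to-one mapping of domain-2 drugs onto domain-1 drugs.

    ``pairs`` holds (domain2_index, domain1_index) tuples; ``matrix_form``
    is the sparse n2 x n1 mapping matrix S with S[i, j] = 1 iff drug i of
    domain 2 and drug j of domain 1 are the same drug.  Each row and each
    column of S carries at most one 1.
    """

    pairs: list[tuple[int, int]]
    n2: int
    n1: int

    def __post_init__(self):
        i2 = [p[0] for p in self.pairs]
        i1 = [p[1] for p in self.pairs]
        if len(set(i2)) != len(i2) or len(set(i1)) != len(i1):
            raise ValueError("anchor map must be one-to-one")
        if i2 and (min(i2) < 0 or max(i2) >= self.n2):
            raise ValueError("domain-2 anchor index out of range")
        if i1 and (min(i1) < 0 or max(i1) >= self.n1):
            raise ValueError("domain-1 anchor index out of range")

    @property
    def matrix_form(self) -> sp.csr_matrix:
        if not self.pairs:
            return sp.csr_matrix((self.n2, self.n1))
        i2, i1 = zip(*self.pairs)
        data = np.ones(len(self.pairs))
        return sp.csr_matrix((data, (i2, i1)), shape=(self.n2, self.n1))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class WeightMatrix:
    """One-class confidence weights: 1 where observed, ``w`` elsewhere."""

    indicator: sp.csr_matrix  # observed-entry indicator I, same shape as X
    w: float

    def __post_init__(self):
        if not (0.0 <= self.w < 1.0):
            raise ValueError(f"w must lie in [0, 1), got {self.w}")
        self.indicator = sp.csr_matrix(self.indicator, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.indicator.shape

    def dense(self) -> np.ndarray:
        return self.w + (1.0 - self.w) * self.indicator.toarray()


@dataclass
class DomainData:
    """One domain: interactions plus both intra-layer similarity graphs."""

    X: BipartiteInteractionMatrix
    A_row: SimilarityMatrix       # drug-drug similarity
    A_col: SimilarityMatrix       # disease-disease or target-target
    L_row: LaplacianPair = field(default=None)
    L_col: LaplacianPair = field(default=None)

    def __post_init__(self):
        n, m = self.X.shape
        if self.A_row.n != n:
            raise ValueError("row similarity size does not match interactions")
        if self.A_col.n != m:
            raise ValueError("column similarity size does not match interactions")
        if self.A_row.ids != self.X.row_ids:
            raise ValueError("row similarity ids do not align with interaction rows")
        if self.A_col.ids != self.X.col_ids:
            raise ValueError("column similarity ids do not align with interaction columns")
        if self.L_row is None:
            self.L_row = build_laplacian(self.A_row)
        if self.L_col is None:
            self.L_col = build_laplacian(self.A_col)


@dataclass
class CrossDomainProblem:
    """The full two-domain input: both networks plus the drug anchor map."""

    domain1: DomainData
    domain2: DomainData
    anchors: AnchorMap

    def __post_init__(self):
        n1 = self.domain1.X.shape[0]
        n2 = self.domain2.X.shape[0]
        if (self.anchors.n2, self.anchors.n1) != (n2, n1):
            raise ValueError("anchor map shape does not match drug counts")

    def domain(self, i: int) -> DomainData:
        if i == 1:
            return self.domain1
        if i == 2:
            return self.domain2
        raise ValueError("domain index must be 1 or 2")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _detect_sep(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def load_interactions(path, domain_tag: str = "drug_disease",
                      header: bool = False) -> BipartiteInteractionMatrix:
    """Read a bipartite edge list: ``<row_id><sep><col_id>[<sep><0|1>]``.

    The separator (tab or comma, else whitespace) is auto-detected from the
    first data line.  A header line is skipped only when ``header=True`` --
    never guessed.  Repeated edges collapse to a single 1; a third column,
    when it parses as 0 or 1, is taken as the interaction value (0 drops
    the edge) and is ignored otherwise.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = 1 if header else 0
    data_lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(lines)]
    data_lines = [(no, ln) for no, ln in data_lines[start:] if ln.strip()]
    if not data_lines:
        raise ValueError(f"{path}: no interaction records found")
    sep = _detect_sep(data_lines[0][1])

    row_ids: list[str] = []
    col_ids: list[str] = []
    row_index: dict[str, int] = {}
    col_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lineno, ln in data_lines:
        parts = ln.split(sep) if sep else ln.split()
        parts = [p.strip() for p in parts]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}: malformed line {lineno}: {ln!r}")
        rid, cid = parts[0], parts[1]
        value = 1
        if len(parts) >= 3 and parts[2] in ("0", "1"):
            value = int(parts[2])
        if rid not in row_index:
            row_index[rid] = len(row_ids)
            row_ids.append(rid)
        if cid not in col_index:
            col_index[cid] = len(col_ids)
            col_ids.append(cid)
        if value == 1:
            edges.add((row_index[rid], col_index[cid]))
    if not edges:
        raise ValueError(f"{path}: no positive interactions")
    rows, cols = zip(*sorted(edges))
    values = sp.csr_matrix(
        (np.ones(len(edges)), (rows, cols)),
        shape=(len(row_ids), len(col_ids)),
    )
    return BipartiteInteractionMatrix(row_ids, col_ids, values, domain_tag)


def write_interactions(X: BipartiteInteractionMatrix, path, sep: str = "\t"):
    """Write the positive entries of ``X`` as an edge list (row order)."""
    with open(path, "w") as fh:
        for i, j in X.positive_pairs():
            fh.write(f"{X.row_ids[i]}{sep}{X.col_ids[j]}\n")


def load_similarity(path, normalize: bool = False) -> SimilarityMatrix:
    """Read a delimited square similarity matrix with id header row/column.

    The matrix is symmetrized as (A + A^T)/2 on load; negative or NaN
    entries are rejected.  Unbounded scores (max > 1) are flagged in
    ``scale_note`` and optionally divided by their maximum when
    ``normalize=True``.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = _detect_sep(first) or r"\s+"
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if ids != col_ids:
        raise ValueError(f"{path}: row and column identifiers differ")
    values = df.to_numpy(dtype=np.float64)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square")
    if np.any(np.isnan(values)):
        raise ValueError(f"{path}: similarity matrix contains NaN")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative similarity entries")
    vmax = values.max(initial=0.0)
    scale_note = "bounded_01" if vmax <= 1.0 + 1e-9 else "unbounded_nonneg"
    if normalize and vmax > 0:
        values = values / vmax
        scale_note = "bounded_01"
    return SimilarityMatrix(ids, values, scale_note)


def write_similarity(A: SimilarityMatrix, path, sep: str = "\t"):
    df = pd.DataFrame(A.values, index=A.ids, columns=A.ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_anchor_map(anchors: AnchorMap, ids2: list[str], ids1: list[str],
                     path, sep: str = "\t"):
    """Export anchors as a two-column (domain2_id, domain1_id) file."""
    with open(path, "w") as fh:
        for i2, i1 in anchors.pairs:
            fh.write(f"{ids2[i2]}{sep}{ids1[i1]}\n")


# ---------------------------------------------------------------------------
# derived matrices
# ---------------------------------------------------------------------------

def build_weight_matrix(X: BipartiteInteractionMatrix, w: float) -> WeightMatrix:
    """Confidence weights: 1 on observed interactions, ``w`` on unknowns."""
    if not (0.0 <= w < 1.0):
        raise ValueError(f"w must lie in [0, 1), got {w}")
    indicator = X.values.copy()
    return WeightMatrix(indicator, w)


def build_laplacian(A: SimilarityMatrix,
                    include_diagonal: bool = True) -> LaplacianPair:
    """Degree matrix D(i,i) = sum_j A(i,j) and graph Laplacian L = D - A.

    ``include_diagonal=False`` zeroes self-similarities before computing
    degrees (both conventions appear in practice; degrees including the
    diagonal are the default).
    """
    values = A.values.copy()
    if not include_diagonal:
        np.fill_diagonal(values, 0.0)
    degree = values.sum(axis=1)
    laplacian = np.diag(degree) - values
    return LaplacianPair(degree=degree, laplacian=laplacian)


def reindex_interactions(X: BipartiteInteractionMatrix, row_ids: list[str],
                         col_ids: list[str]) -> BipartiteInteractionMatrix:
    """Re-express ``X`` over a (super)set universe of identifiers.

    Edge lists cannot represent entities with zero interactions; the
    similarity matrices define the full entity universe, so an interaction
    matrix loaded from an edge list is expanded to that universe (rows and
    columns of isolated entities are all-zero).  An interaction id missing
    from the target universe is an error.
    """
    missing_r = [d for d in X.row_ids if d not in set(row_ids)]
    missing_c = [d for d in X.col_ids if d not in set(col_ids)]
    if missing_r or missing_c:
        raise ValueError(
            f"interaction ids absent from the target universe: "
            f"rows {missing_r[:5]}, cols {missing_c[:5]}"
        )
    lut_r = {d: i for i, d in enumerate(row_ids)}
    lut_c = {d: i for i, d in enumerate(col_ids)}
    coo = X.values.tocoo()
    rows = [lut_r[X.row_ids[i]] for i in coo.row]
    cols = [lut_c[X.col_ids[j]] for j in coo.col]
    values = sp.csr_matrix((coo.data, (rows, cols)),
                           shape=(len(row_ids), len(col_ids)))
    return BipartiteInteractionMatrix(list(row_ids), list(col_ids), values,
                                      X.domain_tag)


def build_anchor_map(ids1: list[str], ids2: list[str]) -> AnchorMap:
    """Anchor by exact identifier equality: same drug id in both domains."""
    if len(set(ids1)) != len(ids1) or len(set(ids2)) != len(ids2):
        raise ValueError("identifier lists must be duplicate-free")
    index1 = {d: i for i, d in enumerate(ids1)}
    pairs = [(i2, index1[d]) for i2, d in enumerate(ids2) if d in index1]
    return AnchorMap(pairs=pairs, n2=len(ids2), n1=len(ids1))


def build_problem(X1: BipartiteInteractionMatrix,
                  Au1: SimilarityMatrix, Av1: SimilarityMatrix,
                  X2: BipartiteInteractionMatrix,
                  Au2: SimilarityMatrix, Av2: SimilarityMatrix,
                  include_diagonal: bool = True) -> CrossDomainProblem:
    """Assemble the two-domain problem; anchors come from shared drug ids."""
    lap = lambda A: build_laplacian(A, include_diagonal=include_diagonal)
    d1 = DomainData(X1, Au1, Av1, lap(Au1), lap(Av1))
    d2 = DomainData(X2, Au2, Av2, lap(Au2), lap(Av2))
    anchors = build_anchor_map(X1.row_ids, X2.row_ids)
    return CrossDomainProblem(d1, d2, anchors)
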