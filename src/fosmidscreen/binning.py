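"""Tetranucleotide-frequency genome binning with an emergent self-organizing map.

Clone sequences are cut into non-overlapping 2 kb fragments (sequences under
2 kb are excluded); each fragment is summarised by its 256-dimensional
tetranucleotide frequency (TNF) vector, counting both strands by default
because insert orientation in a fosmid is arbitrary.  A large ("emergent")
self-organizing map — at least 5.5 neurons per training fragment, toroidal
topology, Gaussian neighbourhood, training radius decaying linearly from 24
to 1 — arranges fragments so that compositionally similar fragments map to
nearby neurons.  The U-matrix (mean codebook distance of each neuron to its
eight toroidal neighbours) exposes cluster boundaries as ridges; genome bins
are the connected low-U regions, and each clone is assigned to the bin
holding the plurality of its fragments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import (
    DataError,
    InsufficientDataError,
    InvalidParameterError,
)

#: The 256 tetranucleotides in lexicographic order (AAAA, AAAC, ..., TTTT).
KMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("N")] = -1
_BASE_CODE[ord("n")] = -1

# involution permutation: code of a 4-mer -> code of its reverse complement
_RC_PERM = np.empty(256, dtype=np.int64)
for _c in range(256):
    digits = [(_c >> (2 * k)) & 3 for k in range(4)]  # last base first
    rc = 0
    for d in digits:  # reverse order and complement (A<->T, C<->G)
        rc = rc * 4 + (3 - d)
    _RC_PERM[_c] = rc


@dataclass
class BinningParams:
    """Fragmentation and TNF feature options."""

    fragment_length: int = 2000
    min_sequence_length: int = 2000
    k: int = 4
    strand_symmetric: bool = True
    feature_normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.k != 4:
            raise InvalidParameterError("word length is fixed at 4 (tetranucleotides)")
        if self.fragment_length < self.k:
            raise InvalidParameterError("fragment_length must be >= k")
        if self.min_sequence_length < self.fragment_length:
            raise InvalidParameterError("min_sequence_length must be >= fragment_length")
        if self.feature_normalization not in ("zscore", "none"):
            raise InvalidParameterError("feature_normalization must be 'zscore' or 'none'")


# ---------------------------------------------------------------------------
# Fragmentation and TNF
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    bad = np.flatnonzero((codes < 0) & (arr != ord("N")) & (arr != ord("n")))
    if bad.size:
        raise DataError(
            f"sequence contains characters outside ACGTN at position {bad[0]}"
        )
    return codes


def fragment_sequence(
    seq: str, params: BinningParams | None = None
) -> list[tuple[int, str]]:
    """Cut a sequence into non-overlapping fragments of ``fragment_length``.

    Returns a list of (offset, subsequence).  Sequences shorter than
    ``min_sequence_length`` yield an empty list (the caller records the
    exclusion); the trailing remainder shorter than one fragment is dropped.
    """
    params = params or BinningParams()
    _encode(seq)  # character validation
    if len(seq) < params.min_sequence_length:
        return []
    L = params.fragment_length
    n = len(seq) // L
    return [(i * L, seq[i * L : (i + 1) * L]) for i in range(n)]


def tnf_vector(fragment: str, strand_symmetric: bool = True) -> np.ndarray:
    """Relative tetranucleotide frequencies of one fragment.

    Counts every overlapping 4-mer window (and, when ``strand_symmetric``,
    the reverse-complement strand as well); windows containing N are
    skipped.  Returns the 256-vector in :data:`KMERS` order, summing to 1,
    or the zero vector if no valid window exists.
    """
    if len(fragment) < 4:
        raise InvalidParameterError("fragment must be at least 4 bp")
    codes = _encode(fragment)
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    words = ((c0 * 4 + c1) * 4 + c2) * 4 + c3
    counts = np.bincount(words[valid], minlength=256).astype(float)
    if strand_symmetric:
        counts = counts + counts[_RC_PERM]
    total = counts.sum()
    if total == 0:
        return np.zeros(256)
    return counts / total


def tnf_matrix(
    sequences: Mapping[str, str], params: BinningParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fragment every sequence and compute the fragments x 256 TNF matrix.

    Returns ``(matrix, fragment_index, excluded)``: *matrix* is indexed by
    fragment id (``<clone_id>:<offset>``) with :data:`KMERS` columns;
    *fragment_index* maps fragment id to clone id and offset; *excluded*
    lists sequences dropped for being shorter than the minimum length.
    """
    params = params or BinningParams()
    ids, rows, index_rows, excluded = [], [], [], []
    for clone_id in sequences:
        frags = fragment_sequence(sequences[clone_id], params)
        if not frags:
            excluded.append(clone_id)
            continue
        for offset, sub in frags:
            fid = f"{clone_id}:{offset}"
            ids.append(fid)
            rows.append(tnf_vector(sub, params.strand_symmetric))
            index_rows.append({"fragment_id": fid, "clone_id": clone_id, "offset": offset})
    matrix = pd.DataFrame(np.array(rows).reshape(-1, 256), index=ids, columns=list(KMERS))
    fragment_index = pd.DataFrame(index_rows, columns=["fragment_id", "clone_id", "offset"])
    return matrix, fragment_index, excluded


def normalize_features(matrix: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Per-column feature normalisation ('zscore' with population SD, or 'none')."""
    if method == "none":
        return matrix
    if method != "zscore":
        raise InvalidParameterError(f"unknown normalisation {method!r}")
    if len(matrix) < 2:
        raise InsufficientDataError("z-scoring needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Emergent SOM
# ---------------------------------------------------------------------------


@dataclass
class EsomParams:
    """Training configuration of the emergent SOM.

    The grid is sized to ``neurons_per_point`` neurons per training vector
    with column/row ratio ``grid_aspect``; topology is toroidal (fixed), the
    neighbourhood Gaussian, and radius/learning rate decay linearly across
    epochs.
    """

    neurons_per_point: float = 5.5
    start_radius: float = 24.0
    end_radius: float = 1.0
    epochs: int = 20
    learning_rate_start: float = 0.5
    learning_rate_end: float = 0.05
    grid_aspect: float = 1.6
    topology: str = "toroidal"
    seed: int = 0
    grid_rows: Optional[int] = None
    grid_cols: Optional[int] = None

    def __post_init__(self) -> None:
        if self.topology != "toroidal":
            raise InvalidParameterError("topology is fixed to 'toroidal'")
        if not (self.start_radius >= self.end_radius >= 0):
            raise InvalidParameterError("need start_radius >= end_radius >= 0")
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if self.neurons_per_point <= 0 or self.grid_aspect <= 0:
            raise InvalidParameterError("neurons_per_point and grid_aspect must be > 0")


@dataclass
class SOMap:
    """A trained toroidal SOM: grid shape, codebook and training log."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (grid_rows * grid_cols, n_features)
    feature_names: list[str]
    training_log: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols

    def coords(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.grid_cols)

    def codebook_grid(self) -> np.ndarray:
        return self.codebook.reshape(self.grid_rows, self.grid_cols, -1)


def esom_grid_shape(n_points: int, params: EsomParams) -> tuple[int, int]:
    """Smallest rows x cols grid with >= ceil(neurons_per_point * n) neurons
    and cols/rows close to ``grid_aspect``."""
    required = math.ceil(params.neurons_per_point * n_points)
    rows = max(2, round(math.sqrt(required / params.grid_aspect)))
    cols = max(2, math.ceil(required / rows))
    return rows, cols


def train_esom(matrix: pd.DataFrame, params: EsomParams | None = None) -> SOMap:
    """Train a toroidal emergent SOM on a (fragments x features) matrix.

    Online training: samples are visited in a seeded random order each
    epoch; for each sample the best-matching unit (minimal Euclidean
    distance) is found and all neurons within the current radius are pulled
    toward the sample with a Gaussian weight (sigma = radius / 2) times the
    learning rate.  Radius and learning rate decay linearly from their start
    to end values over epochs.  The codebook is initialised from a seeded
    uniform distribution over each feature's data range.  Deterministic for
    a fixed seed.
    """
    params = params or EsomParams()
    X = np.ascontiguousarray(matrix.to_numpy(dtype=np.float32))
    n, d = X.shape
    if n < 2:
        raise InsufficientDataError("SOM training needs at least 2 vectors")

    auto_rows, auto_cols = esom_grid_shape(n, params)
    rows = params.grid_rows or auto_rows
    cols = params.grid_cols or auto_cols
    required = math.ceil(params.neurons_per_point * n)
    if rows * cols < required:
        raise InvalidParameterError(
            f"grid {rows}x{cols} smaller than required {required} neurons"
        )

    rng = np.random.default_rng(params.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(rows * cols, d)).astype(np.float32)
    codebook = np.ascontiguousarray(codebook)
    norms = np.einsum("ij,ij->i", codebook, codebook).astype(np.float32)

    row_idx = np.arange(rows)
    col_idx = np.arange(cols)
    log: list[tuple[int, float, float]] = []
    for epoch in range(params.epochs):
        t = epoch / (params.epochs - 1) if params.epochs > 1 else 0.0
        radius = params.start_radius + t * (params.end_radius - params.start_radius)
        lr = params.learning_rate_start + t * (
            params.learning_rate_end - params.learning_rate_start
        )
        log.append((epoch, float(radius), float(lr)))
        sigma2 = 2.0 * max(radius / 2.0, 0.5) ** 2
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            # BMU via |c|^2 - 2 c.x (x^2 constant); ties -> lowest index
            scores = norms - 2.0 * (codebook @ x)
            bmu = int(np.argmin(scores))
            br, bc = divmod(bmu, cols)
            dr = np.abs(row_idx - br)
            dr = np.minimum(dr, rows - dr)
            dc = np.abs(col_idx - bc)
            dc = np.minimum(dc, cols - dc)
            rsel = np.flatnonzero(dr <= radius)
            csel = np.flatnonzero(dc <= radius)
            d2 = dr[rsel, None] ** 2 + dc[None, csel] ** 2
            within = d2 <= radius * radius
            flat = (rsel[:, None] * cols + csel[None, :])[within]
            h = (lr * np.exp(-d2[within] / sigma2)).astype(np.float32)
            sub = codebook[flat]
            sub += h[:, None] * (x - sub)
            codebook[flat] = sub
            norms[flat] = np.einsum("ij,ij->i", sub, sub)
    return SOMap(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook.astype(np.float64),
        feature_names=list(matrix.columns),
        training_log=log,
    )


def best_matching_unit(som: SOMap, vector: np.ndarray) -> tuple[int, int]:
    """Grid coordinate of the neuron with minimal Euclidean distance.

    Ties break to the lowest (row, col) in row-major order.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (som.codebook.shape[1],):
        raise InvalidParameterError(
            f"vector has dimension {v.shape}, codebook expects {som.codebook.shape[1]}"
        )
    d2 = ((som.codebook - v) ** 2).sum(axis=1)
    return som.coords(int(np.argmin(d2)))


def map_fragments(som: SOMap, matrix: pd.DataFrame, chunk: int = 256) -> pd.DataFrame:
    """Best-matching unit and distance for every row of ``matrix``.

    Returns a DataFrame indexed like ``matrix`` with columns row, col,
    distance (Euclidean distance to the BMU codebook).
    """
    X = matrix.to_numpy(dtype=float)
    rows_out = np.empty(len(X), dtype=int)
    cols_out = np.empty(len(X), dtype=int)
    dist_out = np.empty(len(X), dtype=float)
    for start in range(0, len(X), chunk):
        block = X[start : start + chunk]
        d2 = cdist(block, som.codebook, metric="sqeuclidean")
        bmu = d2.argmin(axis=1)
        rows_out[start : start + chunk] = bmu // som.grid_cols
        cols_out[start : start + chunk] = bmu % som.grid_cols
        dist_out[start : start + chunk] = np.sqrt(d2[np.arange(len(block)), bmu])
    return pd.DataFrame(
        {"row": rows_out, "col": cols_out, "distance": dist_out}, index=matrix.index
    )


def compute_umatrix(som: SOMap) -> np.ndarray:
    """Mean Euclidean codebook distance of each neuron to its 8 toroidal
    neighbours (the classical U-matrix height)."""
    grid = som.codebook_grid()
    heights = np.zeros((som.grid_rows, som.grid_cols))
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for dr, dc in shifts:
        neigh = np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
        heights += np.sqrt(((grid - neigh) ** 2).sum(axis=-1))
    return heights / len(shifts)


# ---------------------------------------------------------------------------
# Bin extraction and clone assignment
# ---------------------------------------------------------------------------


@dataclass
class BinPartition:
    """Neuron -> bin labelling of a trained map (0 = unassigned/boundary)."""

    labels: np.ndarray  # (grid_rows, grid_cols) int
    method: str
    params: dict = field(default_factory=dict)

    @property
    def bin_ids(self) -> list[int]:
        return sorted(int(b) for b in np.unique(self.labels) if b != 0)

    def bin_sizes(self) -> dict[int, int]:
        return {b: int((self.labels == b).sum()) for b in self.bin_ids}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _toroidal_components(mask: np.ndarray) -> np.ndarray:
    """8-connected components of a boolean grid with wrap-around edges."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return labels
    uf = _UnionFind(n + 1)
    rows, cols = mask.shape
    # merge labels that touch across the top/bottom and left/right seams
    for c in range(cols):
        a = labels[0, c]
        if a:
            for dc in (-1, 0, 1):
                b = labels[rows - 1, (c + dc) % cols]
                if b:
                    uf.union(a, b)
    for r in range(rows):
        a = labels[r, 0]
        if a:
            for dr in (-1, 0, 1):
                b = labels[(r + dr) % rows, cols - 1]
                if b:
                    uf.union(a, b)
    roots = {}
    out = np.zeros_like(labels)
    for r in range(rows):
        for c in range(cols):
            lab = labels[r, c]
            if lab:
                root = uf.find(lab)
                out[r, c] = roots.setdefault(root, len(roots) + 1)
    return out


def _kmedoids(codebook: np.ndarray, k: int, seed: int, max_iter: int = 50) -> np.ndarray:
    """Plain PAM-style k-medoids on Euclidean distances."""
    rng = np.random.default_rng(seed)
    n = len(codebook)
    medoids = rng.choice(n, size=k, replace=False)
    d = cdist(codebook, codebook)
    assign = d[:, medoids].argmin(axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[within.argmin()]
        new_assign = d[:, new_medoids].argmin(axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    return assign + 1


def extract_bins(
    som: SOMap,
    umatrix: np.ndarray,
    method: str = "watershed-threshold",
    q: float = 60.0,
    min_neurons: int = 5,
    merge_q: Optional[float] = 85.0,
    k: Optional[int] = None,
    seed: int = 0,
) -> BinPartition:
    """Partition the map into genome bins.

    ``watershed-threshold`` (default, a deterministic stand-in for visual
    map inspection): neurons with U-matrix height at or below the q-th
    percentile form the foreground; toroidal 8-connected foreground
    components seed the bins.  Seed components whose separating ridge is
    itself low — i.e. that remain connected when the threshold is relaxed to
    the ``merge_q``-th percentile — are merged, the way an inspector would
    group patches separated only by shallow valleys rather than true
    inter-genome ridges (``merge_q=None`` disables this).  Merged components
    smaller than ``min_neurons`` are folded into label 0
    (boundary/unassigned).  ``kmedoids`` clusters the codebook directly into
    ``k`` bins.  A manual labelling can be supplied downstream as a plain
    neuron-label table instead.
    """
    if method == "watershed-threshold":
        if not (0 < q <= 100):
            raise InvalidParameterError("q must lie in (0, 100]")
        if merge_q is not None and not (0 < merge_q <= 100):
            raise InvalidParameterError("merge_q must lie in (0, 100]")
        cut = np.percentile(umatrix, q)
        mask = umatrix <= cut
        labels = _toroidal_components(mask)
        if merge_q is not None and merge_q > q:
            # every strict component is nested inside exactly one component
            # of the relaxed mask; shared membership merges them
            relaxed = _toroidal_components(umatrix <= np.percentile(umatrix, merge_q))
            merged = np.zeros_like(labels)
            for b in np.unique(labels):
                if b == 0:
                    continue
                super_ids = relaxed[labels == b]
                merged[labels == b] = int(super_ids[0])
            labels = merged
        for b in np.unique(labels):
            if b != 0 and (labels == b).sum() < min_neurons:
                labels[labels == b] = 0
        # compact labels to 1..n
        remap = {old: new for new, old in enumerate(
            sorted(b for b in np.unique(labels) if b != 0), start=1)}
        labels = np.vectorize(lambda v: remap.get(v, 0))(labels) if remap else labels
        return BinPartition(labels=labels.astype(int), method=method,
                            params={"q": q, "min_neurons": min_neurons,
                                    "merge_q": merge_q})
    if method == "kmedoids":
        if not k or k < 1:
            raise InvalidParameterError("kmedoids needs k >= 1")
        assign = _kmedoids(som.codebook, k, seed)
        return BinPartition(
            labels=assign.reshape(som.grid_rows, som.grid_cols),
            method=method,
            params={"k": k},
        )
    raise InvalidParameterError(f"unknown bin extraction method {method!r}")


def assign_clones(
    partition: BinPartition,
    fragment_bmus: pd.DataFrame,
    fragment_index: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each clone to the bin holding the plurality of its fragments.

    ``fragment_bmus`` (from :func:`map_fragments`) carries row/col/distance
    per fragment; ``fragment_index`` maps fragments to clones.  Fragments on
    unassigned neurons (label 0) are ignored unless a clone has no labelled
    fragment at all.  Ties are resolved toward the bin with the smaller mean
    fragment-to-codebook distance and flagged.

    Returns a DataFrame with columns clone_id, bin, n_fragments,
    majority_fraction, tie_flag.
    """
    merged = fragment_index.set_index("fragment_id").join(fragment_bmus, how="inner")
    merged["bin"] = partition.labels[merged["row"], merged["col"]]
    records = []
    for clone_id, grp in merged.groupby("clone_id", sort=True):
        labels = grp["bin"].to_numpy()
        considered = grp[grp["bin"] != 0] if (labels != 0).any() else grp
        counts = considered.groupby("bin").size()
        top = counts.max()
        tied = sorted(counts[counts == top].index)
        tie = len(tied) > 1
        if tie:
            mean_dist = {
                b: considered.loc[considered["bin"] == b, "distance"].mean() for b in tied
            }
            winner = min(tied, key=lambda b: (mean_dist[b], b))
        else:
            winner = tied[0]
        records.append(
            {
                "clone_id": clone_id,
                "bin": int(winner),
                "n_fragments": int(len(grp)),
                "majority_fraction": float(top / len(considered)),
                "tie_flag": bool(tie),
            }
        )
    return pd.DataFrame(
        records, columns=["clone_id", "bin", "n_fragments", "majority_fraction", "tie_flag"]
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class BinningResult:
    tnf: pd.DataFrame
    normalized: pd.DataFrame
    fragment_index: pd.DataFrame
    excluded: list[str]
    som: SOMap
    umatrix: np.ndarray
    partition: BinPartition
    assignments: pd.DataFrame
    fragment_bmus: pd.DataFrame


def bin_clones(
    sequences: Mapping[str, str],
    binning: BinningParams | None = None,
    esom: EsomParams | None = None,
    extract_kwargs: Optional[dict] = None,
) -> BinningResult:
    """Run the full binning chain: fragment -> TNF -> normalise -> train ->
    U-matrix -> extract bins -> majority-vote clone assignment."""
    binning = binning or BinningParams()
    esom = esom or EsomParams()
    matrix, fragment_index, excluded = tnf_matrix(sequences, binning)
    normalized = normalize_features(matrix, binning.feature_normalization)
    som = train_esom(normalized, esom)
    umatrix = compute_umatrix(som)
    partition = extract_bins(som, umatrix, **(extract_kwargs or {}))
    bmus = map_fragments(som, normalized)
    assignments = assign_clones(partition, bmus, fragment_index)
    return BinningResult(
        tnf=matrix,
        normalized=normalized,
        fragment_index=fragment_index,
        excluded=excluded,
        som=som,
        umatrix=umatrix,
        partition=partition,
        assignments=assignments,
        fragment_bmus=bmus,
    )
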