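"""Per-residue neighbour lists and numeric pair encodings for the scorer.

Each residue i is paired with its (up to) 10 spatially closest residues at
sequence separation ≥ 6.  An ordered pair (i, j) is encoded as a fixed-length
real vector built from a sequence window of one residue either side of both i
and j: amino-acid / secondary-structure / accessibility one-hots, the cosine
of the virtual-bond angle at each window residue, all pairwise Euclidean
distances among the six window residues (expressed in units of 10 Å, see
``DIST_SCALE``), and pad flags for window positions that fall off the chain.  The encoding depends on the conformation only
through distances and bond-angle cosines, so it is invariant under rigid
motion and under mirror reflection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import ACC_CLASSES, SS3_CLASSES, CaTrace

MAX_NEIGHBORS = 10
MIN_SEQ_SEP = 6  # "sequence separation > 5"

#: distances enter the encoding in units of 10 Å (nanometres): the raw Å
#: values have ~50× the variance of the one-hot features and that
#: conditioning mismatch stalls gradient-descent training
DIST_SCALE = 0.1

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard; anything else -> unknown
N_AA = len(AA_ALPHABET) + 1  # +1 unknown bucket

_WINDOW_OFFSETS = (-1, 0, 1)
_N_WINDOW = 2 * len(_WINDOW_OFFSETS)  # residues i-1..i+1, j-1..j+1
_N_PAIRS = _N_WINDOW * (_N_WINDOW - 1) // 2  # 15 distances
_PER_RESIDUE = N_AA + len(SS3_CLASSES) + len(ACC_CLASSES)  # 26

#: total encoding dimensionality: 6×26 one-hots + 15 distances + 6 cosines
#: + 6 pad flags
ENCODING_DIM = _N_WINDOW * _PER_RESIDUE + _N_PAIRS + _N_WINDOW + _N_WINDOW

_AA_INDEX = {aa: k for k, aa in enumerate(AA_ALPHABET)}
_SS_INDEX = {s: k for k, s in enumerate(SS3_CLASSES)}
_ACC_INDEX = {a: k for k, a in enumerate(ACC_CLASSES)}
_PAIR_IDX = list(combinations(range(_N_WINDOW), 2))


@dataclass(frozen=True)
class NeighborList:
    """Per-residue ordered neighbour index lists C_i (ascending distance)."""

    lists: tuple

    def __len__(self):
        return len(self.lists)

    def __getitem__(self, i):
        return self.lists[i]

    @property
    def n_pairs(self) -> int:
        return sum(len(c) for c in self.lists)


def neighbor_list(
    trace: CaTrace | np.ndarray,
    max_neighbors: int = MAX_NEIGHBORS,
    min_sep: int = MIN_SEQ_SEP,
) -> NeighborList:
    """The up-to-``max_neighbors`` closest residues to each i at sequence
    separation ≥ ``min_sep``, sorted by ascending distance (ties: lower
    index first)."""
    coords = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, float)
    L = len(coords)
    D = squareform(pdist(coords))
    lists = []
    idx = np.arange(L)
    for i in range(L):
        allowed = idx[np.abs(idx - i) >= min_sep]
        if len(allowed) == 0:
            lists.append(())
            continue
        order = np.lexsort((allowed, D[i, allowed]))
        lists.append(tuple(allowed[order[:max_neighbors]].tolist()))
    return NeighborList(tuple(lists))


def _static_residue_features(trace: CaTrace) -> np.ndarray:
    """(L, 26) per-residue one-hot block: amino acid, ss3, acc."""
    if not trace.has_features:
        raise ValueError(
            "trace has no ss3/acc features; attach predicted features first"
        )
    L = len(trace)
    F = np.zeros((L, _PER_RESIDUE))
    for k, (aa, ss, acc) in enumerate(zip(trace.sequence, trace.ss3, trace.acc)):
        F[k, _AA_INDEX.get(aa, N_AA - 1)] = 1.0
        F[k, N_AA + _SS_INDEX[ss]] = 1.0
        F[k, N_AA + len(SS3_CLASSES) + _ACC_INDEX[acc]] = 1.0
    return F


def _bond_angle_cosines(coords: np.ndarray) -> np.ndarray:
    """cos of the angle between consecutive virtual bonds at each residue;
    0 at the chain termini where the angle is undefined."""
    L = len(coords)
    cosines = np.zeros(L)
    if L >= 3:
        b = np.diff(coords, axis=0)
        norms = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.einsum("ij,ij->i", b[:-1], b[1:]) / (norms[:-1] * norms[1:])
        cosines[1:-1] = np.clip(np.nan_to_num(c), -1.0, 1.0)
    return cosines


class ConformationEncoder:
    """Encodes (i, j) pairs of a trace; caches the sequence-static blocks.

    The static one-hot block depends only on sequence and features, so a
    single encoder can re-encode many conformations of the same target
    cheaply (as the annealing search does).
    """

    def __init__(self, trace: CaTrace):
        self._static = _static_residue_features(trace)
        self.L = len(trace)

    def _window(self, centers: np.ndarray):
        """(P, 6) window indices (clipped) and (P, 6) validity flags."""
        offs = np.array(_WINDOW_OFFSETS)
        win_i = centers[:, 0][:, None] + offs[None, :]
        win_j = centers[:, 1][:, None] + offs[None, :]
        win = np.concatenate([win_i, win_j], axis=1)  # (P, 6)
        valid = (win >= 0) & (win < self.L)
        return np.clip(win, 0, self.L - 1), valid

    def encode_pairs(self, coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
        """Encode an array of ordered (i, j) pairs for one conformation.

        Returns a (P, ENCODING_DIM) array.
        """
        coords = np.asarray(coords, float)
        pairs = np.asarray(pairs, int).reshape(-1, 2)
        P = len(pairs)
        if P == 0:
            return np.zeros((0, ENCODING_DIM))
        win, valid = self._window(pairs)
        fvalid = valid.astype(float)

        static = self._static[win] * fvalid[:, :, None]  # (P, 6, 26)

        wcoords = coords[win]  # (P, 6, 3)
        a, b = zip(*_PAIR_IDX)
        a, b = np.array(a), np.array(b)
        diffs = wcoords[:, a, :] - wcoords[:, b, :]
        dists = DIST_SCALE * np.linalg.norm(diffs, axis=2)  # (P, 15)
        pair_valid = fvalid[:, a] * fvalid[:, b]
        dists *= pair_valid

        cosines = _bond_angle_cosines(coords)[win] * fvalid  # (P, 6)
        pad_flags = 1.0 - fvalid

        return np.concatenate(
            [static.reshape(P, -1), dists, cosines, pad_flags], axis=1
        )


def encode_pair(trace: CaTrace, i: int, j: int) -> np.ndarray:
    """Encoding vector for a single ordered pair (i, j), |i−j| ≥ 6."""
    if abs(i - j) < MIN_SEQ_SEP:
        raise ValueError(f"pair ({i}, {j}) violates minimum sequence separation")
    enc = ConformationEncoder(trace)
    return enc.encode_pairs(trace.coords, np.array([[i, j]]))[0]


@dataclass(frozen=True)
class ConformationEncoding:
    """All pair encodings of one conformation, grouped by residue.

    ``X`` stacks the per-pair vectors; ``groups[i]`` gives the row slice of
    residue i's pairs (one row per neighbour j ∈ C_i).
    """

    X: np.ndarray
    pairs: np.ndarray  # (P, 2) ordered (i, j)
    neighbor: NeighborList

    @property
    def n_pairs(self) -> int:
        return len(self.X)

    def rows_for_residue(self, i: int) -> np.ndarray:
        return self.X[self.pairs[:, 0] == i]


def encode_conformation(
    trace: CaTrace,
    encoder: ConformationEncoder | None = None,
    coords: np.ndarray | None = None,
) -> ConformationEncoding:
    """Encode every (i, j ∈ C_i) pair of a conformation.

    ``encoder`` and ``coords`` allow reuse of the static blocks across the
    conformations of one target during search.
    """
    if encoder is None:
        encoder = ConformationEncoder(trace)
    if coords is None:
        coords = trace.coords
    nl = neighbor_list(coords)
    pairs = np.array(
        [(i, j) for i, cs in enumerate(nl.lists) for j in cs], dtype=int
    ).reshape(-1, 2)
    X = encoder.encode_pairs(coords, pairs)
    return ConformationEncoding(X, pairs, nl)
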