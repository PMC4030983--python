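"""Structure-comparison quantities.

Contact maps and the recall+precision quality label q ∈ [−1, 1] used as the
training target; Kabsch least-squares superposition and RMSD; the Global
Distance Test score GDT = (GDT₁ + GDT₂ + GDT₄ + GDT₈)/4 computed with a
deterministic multi-seed superposition search; mutual-GDT matrices over model
sets and their mean, the m statistic used as a funnel-likeness proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import CaTrace

#: contact definition used for the quality label: Cα–Cα distance and the
#: minimum sequence separation matching the neighbour-list filter
CONTACT_THRESHOLD = 8.0
CONTACT_MIN_SEP = 6

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class ContactMap:
    """Set of residue pairs (i < j) within ``threshold`` Å at sequence
    separation ≥ ``min_sep``."""

    length: int
    contacts: frozenset
    threshold: float
    min_sep: int


def contact_map(
    trace: CaTrace | np.ndarray,
    threshold: float = CONTACT_THRESHOLD,
    min_sep: int = CONTACT_MIN_SEP,
) -> ContactMap:
    coords = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, float)
    L = len(coords)
    D = squareform(pdist(coords))
    i, j = np.triu_indices(L, k=min_sep)
    hit = D[i, j] <= threshold
    pairs = frozenset(zip(i[hit].tolist(), j[hit].tolist()))
    return ContactMap(L, pairs, threshold, min_sep)


def contact_quality(
    model: CaTrace,
    native: CaTrace,
    threshold: float = CONTACT_THRESHOLD,
    min_sep: int = CONTACT_MIN_SEP,
) -> float | None:
    """Recall + precision of the model's contact map against the native's,
    rescaled to [−1, 1]: q = recall + precision − 1.

    Returns None when the native has no contacts (the label is meaningless
    and such references are excluded from training).  A model with no
    contacts has precision 0.
    """
    if len(model) != len(native):
        raise ValueError("model and native must have equal length")
    cm = contact_map(model, threshold, min_sep).contacts
    cn = contact_map(native, threshold, min_sep).contacts
    if not cn:
        return None
    inter = len(cm & cn)
    recall = inter / len(cn)
    precision = inter / len(cm) if cm else 0.0
    return recall + precision - 1.0


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(A: np.ndarray, B: np.ndarray):
    """Least-squares proper-rotation superposition of B onto A.

    Returns ``(R, t, rmsd)`` with the row-vector convention
    ``B @ R + t ≈ A``; reflections are never used, so mirror images keep a
    positive RMSD.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if A.ndim != 2 or A.shape[1] != 3 or len(A) < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = ca - cb @ R
    rmsd = float(np.sqrt(np.mean(np.sum((B @ R + t - A) ** 2, axis=1))))
    return R, t, rmsd


def rmsd(model: CaTrace | np.ndarray, native: CaTrace | np.ndarray) -> float:
    """Cα RMSD after optimal superposition."""
    A = native.coords if isinstance(native, CaTrace) else np.asarray(native, float)
    B = model.coords if isinstance(model, CaTrace) else np.asarray(model, float)
    return kabsch_superpose(A, B)[2]


def _batched_weighted_rotations(A, B, W):
    """Proper rotations superposing B onto A under per-point weights.

    A, B: (L, 3); W: (S, L) non-negative weights.  Returns rotated-B sets of
    shape (S, L, 3) already translated onto A's weighted frame.
    """
    wsum = W.sum(axis=1)[:, None]
    ca = (W[:, :, None] * A).sum(axis=1) / wsum  # (S, 3)
    cb = (W[:, :, None] * B).sum(axis=1) / wsum
    Ac = A[None, :, :] - ca[:, None, :]
    Bc = B[None, :, :] - cb[:, None, :]
    H = np.einsum("sl,sli,slj->sij", W, Bc, Ac)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("sij,sjk->sik", U, Vt))
    D = np.repeat(np.eye(3)[None, :, :], len(W), axis=0)
    D[:, 2, 2] = det
    R = np.einsum("sij,sjk,skl->sil", U, D, Vt)
    # rotate the *full* chain about B's weighted centroid, translate onto A's
    Bfull = B[None, :, :] - cb[:, None, :]
    return np.einsum("sli,sik->slk", Bfull, R) + ca[:, None, :]


def _gdt_counts(model: np.ndarray, native: np.ndarray, thresholds=GDT_THRESHOLDS,
                max_iter: int = 10):
    """Best per-threshold counts of model atoms within X Å of their native
    counterparts, over a deterministic superposition search.

    Seeds: the global superposition plus one per contiguous window of length
    max(5, L//10); each seed is iteratively re-superposed on the atoms
    currently within the threshold until the in-threshold set is stable.
    """
    L = len(native)
    w = max(5, L // 10)
    starts = np.arange(0, L - w + 1)
    S = len(starts) + 1
    W0 = np.zeros((S, L))
    W0[0] = 1.0  # global superposition seed
    for s, st in enumerate(starts, start=1):
        W0[s, st : st + w] = 1.0
    Bs = _batched_weighted_rotations(native, model, W0)
    dist = np.linalg.norm(Bs - native[None, :, :], axis=2)  # (S, L)

    best = np.zeros(len(thresholds), dtype=int)
    for ti, thr in enumerate(thresholds):
        mask = dist <= thr
        best_count = int(mask.sum(axis=1).max())
        for _ in range(max_iter):
            ok = mask.sum(axis=1) >= 3
            Wm = np.where(mask, 1.0, 0.0)
            Wm[~ok] = W0[~ok]  # degenerate subsets keep their seed weights
            Bs2 = _batched_weighted_rotations(native, model, Wm)
            d2 = np.linalg.norm(Bs2 - native[None, :, :], axis=2)
            new_mask = d2 <= thr
            best_count = max(best_count, int(new_mask.sum(axis=1).max()))
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        best[ti] = best_count
    return best


def gdt_score(model: CaTrace | np.ndarray, native: CaTrace | np.ndarray) -> float:
    """GDT-TS as the mean of GDT_X at X = 1, 2, 4, 8 Å, as a fraction in
    [0, 1]; GDT_X is the largest fraction of atoms within X Å of their native
    counterparts found by the superposition search."""
    A = native.coords if isinstance(native, CaTrace) else np.asarray(native, float)
    B = model.coords if isinstance(model, CaTrace) else np.asarray(model, float)
    if A.shape != B.shape:
        raise ValueError("model and native must have equal length")
    counts = _gdt_counts(B, A)
    return float(counts.mean() / len(A))


def gdt_per_threshold(model, native) -> dict:
    A = native.coords if isinstance(native, CaTrace) else np.asarray(native, float)
    B = model.coords if isinstance(model, CaTrace) else np.asarray(model, float)
    counts = _gdt_counts(B, A)
    return {x: c / len(A) for x, c in zip(GDT_THRESHOLDS, counts)}


# ---------------------------------------------------------------------------
# Mutual-GDT matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutualGdtMatrix:
    """Symmetric n×n matrix of pairwise model GDT scores, unit diagonal."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if not np.allclose(M, M.T):
            raise ValueError("M must be symmetric")
        if np.any((M < 0) | (M > 1)):
            raise ValueError("entries must lie in [0, 1]")
        object.__setattr__(self, "M", M)

    @property
    def n(self) -> int:
        return len(self.M)


def mutual_gdt_matrix(models) -> MutualGdtMatrix:
    """GDT score between every pair of models; each pair computed once."""
    coords = [m.coords if isinstance(m, CaTrace) else np.asarray(m, float) for m in models]
    n = len(coords)
    if n < 1:
        raise ValueError("need at least one model")
    L = len(coords[0])
    if any(len(c) != L for c in coords):
        raise ValueError("all models must have equal length")
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = gdt_score(coords[j], coords[i])
    return MutualGdtMatrix(M)


def mean_mutual_gdt(M: MutualGdtMatrix) -> float:
    """m statistic: mean of the mutual-GDT matrix over all n² entries,
    diagonal included."""
    return float(M.M.mean())
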