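"""Synthetic structures, features, snippet libraries and decoys.

This module generates idealized but geometrically plausible Cα-trace
"proteins" so that the full pipeline — encoding, scoring, annealing search,
iterative training and model selection — can be exercised without any
structure database.  Helices follow ideal Cα-helix geometry (2.3 Å radius,
1.5 Å rise, 100°/residue, giving the canonical ~3.8 Å Cα spacing), strands
are near-extended zig-zags, coils are self-avoiding random walks; segments
are packed by seeded rigid placement that rejects steric clashes and biases
segments towards the existing centroid so that long-range contacts exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .metrics import contact_map, contact_quality
from .reconstructor import SNIPPET_LEN, Snippet, SnippetLibrary
from .structures import CaTrace, random_extended_trace

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TURN = np.deg2rad(100.0)
MIN_NONBONDED = 3.73

_AA = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "AVLIMFWC"
_POLAR = "RNDQEGHKPSTY"


@dataclass(frozen=True)
class TopologySpec:
    """Ordered (kind, length) segments, kind ∈ {helix, strand, coil}."""

    segments: tuple

    def __post_init__(self):
        segs = tuple((str(k), int(n)) for k, n in self.segments)
        if any(k not in ("helix", "strand", "coil") for k, _ in segs):
            raise ValueError("segment kinds must be helix/strand/coil")
        if any(n < 1 for _, n in segs):
            raise ValueError("segment lengths must be >= 1")
        if sum(n for _, n in segs) < SNIPPET_LEN:
            raise ValueError(f"total length must be >= {SNIPPET_LEN}")
        object.__setattr__(self, "segments", segs)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.segments)

    @property
    def ss3(self) -> str:
        code = {"helix": "H", "strand": "E", "coil": "C"}
        return "".join(code[k] * n for k, n in self.segments)


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack([
        HELIX_RADIUS * np.cos(HELIX_TURN * t),
        HELIX_RADIUS * np.sin(HELIX_TURN * t),
        HELIX_RISE * t,
    ], axis=1)


def _strand_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    zig = 0.95 * (t % 2)
    dx = np.sqrt(3.8**2 - 0.95**2)
    return np.stack([dx * t, zig, np.zeros(n)], axis=1)


def _coil_coords(n: int, rng) -> np.ndarray:
    coords = np.zeros((n, 3))
    for k in range(1, n):
        for _ in range(50):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = coords[k - 1] + rng.uniform(3.73, 3.87) * v
            if k < 2 or np.min(np.linalg.norm(coords[: k - 1] - cand, axis=1)) >= MIN_NONBONDED:
                coords[k] = cand
                break
        else:
            coords[k] = coords[k - 1] + rng.uniform(3.73, 3.87) * v
    return coords


def _random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def synthetic_native(spec: TopologySpec, seed: int, max_restarts: int = 40) -> CaTrace:
    """Build a packed Cα trace realizing ``spec``; deterministic per seed.

    Raises RuntimeError (suggesting a new seed) if no clash-free packing is
    found within the retry budget.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = _try_pack(spec, rng)
        if coords is not None:
            return CaTrace(_sequence_for(coords, rng), coords)
    raise RuntimeError("packing failed after bounded retries; try another seed")


def _sequence_for(coords: np.ndarray, rng, adherence: float = 0.8) -> str:
    """Sequence with a realistic hydrophobic pattern: buried positions
    (neighbour count within 10 Å above the median) draw hydrophobic
    residues with probability ``adherence``, exposed ones polar residues —
    real sequences encode burial, uniform-random ones do not."""
    D = cdist(coords, coords)
    counts = (D < 10.0).sum(axis=1) - 1
    median = np.median(counts)
    seq = []
    for c in counts:
        core = _HYDROPHOBIC if c > median else _POLAR
        other = _POLAR if c > median else _HYDROPHOBIC
        pool = core if rng.random() < adherence else other
        seq.append(pool[rng.integers(len(pool))])
    return "".join(seq)


def _try_pack(spec: TopologySpec, rng):
    placed = None
    for kind, n in spec.segments:
        if kind == "helix":
            seg = _helix_coords(n)
        elif kind == "strand":
            seg = _strand_coords(n)
        else:
            seg = _coil_coords(n, rng)
        if placed is None:
            placed = seg @ _random_rotation(rng).T
            continue
        ok = False
        for _ in range(200):
            R = _random_rotation(rng)
            seg_r = (seg - seg[0]) @ R.T
            # junction direction biased towards the centroid for compactness
            to_center = np.mean(placed, axis=0) - placed[-1]
            nc = np.linalg.norm(to_center)
            bias = to_center / nc if nc > 1e-9 else np.zeros(3)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            d = 1.2 * bias + v
            d /= np.linalg.norm(d)
            origin = placed[-1] + rng.uniform(3.73, 3.87) * d
            cand = seg_r + origin
            D = cdist(placed, cand)
            # the junction pair (last placed, first new) is bonded
            D_check = D.copy()
            D_check[-1, 0] = np.inf
            if D_check.min() >= MIN_NONBONDED and _self_ok(cand):
                placed = np.vstack([placed, cand])
                ok = True
                break
        if not ok:
            return None
    return placed


def _self_ok(seg: np.ndarray) -> bool:
    if len(seg) < 3:
        return True
    d = pdist(seg)
    i, j = np.triu_indices(len(seg), k=2)
    full = np.triu_indices(len(seg), k=1)
    sep = full[1] - full[0]
    return bool(np.all(d[sep >= 2] >= MIN_NONBONDED - 1e-9))


def synthetic_features(trace: CaTrace, spec: TopologySpec,
                       noise_rate: float = 0.0, seed: int = 0) -> CaTrace:
    """Attach ss3 labels from the spec segments and a burial-proxy acc label
    (neighbour count within 10 Å above the median → buried); optional label
    noise emulates 1D-predictor error."""
    if spec.total_length != len(trace):
        raise ValueError("spec length does not match trace")
    rng = np.random.default_rng(seed)
    ss3 = list(spec.ss3)
    D = cdist(trace.coords, trace.coords)
    counts = (D < 10.0).sum(axis=1) - 1
    median = np.median(counts)
    acc = ["buried" if c > median else "exposed" for c in counts]
    if noise_rate > 0:
        for k in range(len(trace)):
            if rng.random() < noise_rate:
                ss3[k] = rng.choice([s for s in "HEC" if s != ss3[k]])
            if rng.random() < noise_rate:
                acc[k] = "buried" if acc[k] == "exposed" else "exposed"
    return CaTrace(trace.sequence, trace.coords.copy(), "".join(ss3), tuple(acc))


def synthetic_snippets(
    native: CaTrace,
    n_per_pos: int = 5,
    native_fraction: float = 0.3,
    noise_A: float = 0.0,
    seed: int = 0,
) -> SnippetLibrary:
    """Library covering every window start 0..L−9: with probability
    ``native_fraction`` a (possibly jittered) copy of the native window,
    otherwise a 9-mer from an unrelated random chain."""
    L = len(native)
    if L < SNIPPET_LEN:
        raise ValueError("native shorter than the snippet window")
    rng = np.random.default_rng(seed)
    lib = SnippetLibrary()
    for pos in range(L - SNIPPET_LEN + 1):
        for k in range(n_per_pos):
            if rng.random() < native_fraction:
                coords = native.coords[pos : pos + SNIPPET_LEN].copy()
                if noise_A > 0:
                    coords = _jitter_snippet(coords, noise_A, rng)
                src = f"native:{pos}"
            else:
                decoyc = random_extended_trace("A" * SNIPPET_LEN, rng).coords
                coords = decoyc
                src = f"random:{pos}.{k}"
            lib.add(Snippet(coords, src, pos))
    return lib


def _jitter_snippet(coords: np.ndarray, noise_A: float, rng, max_tries: int = 30):
    for _ in range(max_tries):
        cand = coords + rng.normal(scale=noise_A, size=coords.shape)
        d = np.linalg.norm(np.diff(cand, axis=0), axis=1)
        if np.all((d >= 2.5) & (d <= 4.5)):
            return cand
    return coords


def perturbed_trace(native: CaTrace, magnitude: float, seed: int) -> CaTrace:
    """Gaussian coordinate displacement of scale ``magnitude`` Å followed by
    a chain walk that clamps every consecutive distance into [3.6, 4.0]."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    disp = native.coords + rng.normal(scale=magnitude, size=native.coords.shape)
    coords = np.empty_like(disp)
    coords[0] = disp[0]
    for k in range(1, len(disp)):
        v = disp[k] - disp[k - 1]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            v, norm = np.array([3.8, 0.0, 0.0]), 3.8
        coords[k] = coords[k - 1] + v * (np.clip(norm, 3.6, 4.0) / norm)
    return native.with_coords(coords)


def perturbed_decoy(native: CaTrace, magnitude: float, seed: int):
    """(trace, q) pair: perturbed conformation labelled by contact-map
    quality against the native."""
    trace = perturbed_trace(native, magnitude, seed)
    q = contact_quality(trace, native)
    return trace, q


def default_suite_specs(n_targets: int = 10, min_len: int = 30, max_len: int = 60,
                        seed: int = 0) -> list:
    """Mixed-topology specs emulating short single-domain proteins."""
    rng = np.random.default_rng(seed)
    shapes = [
        ("helix", "coil", "helix"),
        ("helix", "coil", "strand", "coil", "strand"),
        ("strand", "coil", "strand", "coil", "helix"),
        ("coil", "helix", "coil", "helix", "coil"),
    ]
    specs = []
    for t in range(n_targets):
        kinds = shapes[t % len(shapes)]
        total = int(rng.integers(min_len, max_len + 1))
        n_coil = sum(1 for k in kinds if k == "coil")
        n_struct = len(kinds) - n_coil
        coil_len = 4
        struct_len = max(5, (total - coil_len * n_coil) // max(n_struct, 1))
        segs = [(k, coil_len if k == "coil" else struct_len) for k in kinds]
        specs.append(TopologySpec(tuple(segs)))
    return specs


@dataclass
class Target:
    """A synthetic training/evaluation target: native with features attached
    plus its snippet library."""

    target_id: str
    native: CaTrace
    library: SnippetLibrary
    spec: TopologySpec


def make_suite(
    n_targets: int = 10,
    seed: int = 0,
    min_len: int = 30,
    max_len: int = 60,
    n_per_pos: int = 5,
    native_fraction: float = 0.3,
    noise_A: float = 0.3,
) -> list:
    """Full synthetic suite: packed natives, geometry-derived features and
    mixed native/random snippet libraries.

    Natives are regenerated (bounded retries) until they carry a realistic
    number of long-range contacts — max(4, L/8) at the 8 Å / sep ≥ 6
    definition — since a contact-free "native" has no defined quality label
    and no folded character.
    """
    rng = np.random.default_rng(seed)
    specs = default_suite_specs(n_targets, min_len, max_len, seed=rng.integers(2**31))
    suite = []
    for t, spec in enumerate(specs):
        for _ in range(60):
            try:
                native = synthetic_native(spec, seed=int(rng.integers(2**31)))
            except RuntimeError:
                continue
            if len(contact_map(native).contacts) >= max(4, spec.total_length // 8):
                break
        else:
            raise RuntimeError(f"could not generate a compact native for target {t}")
        native = synthetic_features(native, spec)
        lib = synthetic_snippets(
            native, n_per_pos=n_per_pos, native_fraction=native_fraction,
            noise_A=noise_A, seed=int(rng.integers(2**31)),
        )
        suite.append(Target(f"synt{t:03d}", native, lib, spec))
    return suite
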