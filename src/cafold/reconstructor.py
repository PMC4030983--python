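"""Fragment-insertion simulated annealing over Cα traces.

The search perturbs the current model by replacing the geometry of a
9-residue window with a snippet drawn from a library of template fragments,
re-scores the perturbed model with the pairwise-interaction network, and
accepts or rejects by the Metropolis criterion under a quadratically cooled
temperature.  Insertion sites are biased (80% of attempts) towards positions
whose predicted secondary structure is coil.  The pseudo-energy of a model is

    P_E = L − L·O01 + C

with O01 the network output rescaled to [0, 1] and C a clash penalty
counting residue pairs closer than 3.73 Å.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .encoding import ConformationEncoder, encode_conformation
from .nnpif import NNPIFModel, forward
from .structures import CaTrace, InternalCoords, anchor_from_frame, from_internal, to_internal

logger = logging.getLogger(__name__)

SNIPPET_LEN = 9
CLASH_THRESHOLD = 3.73
T_FLOOR = 1e-6


@dataclass(frozen=True)
class Snippet:
    """A 9-residue template fragment assignable to target position
    ``target_pos`` (0-based window start)."""

    coords: np.ndarray
    source: str
    target_pos: int

    def __post_init__(self):
        coords = np.asarray(self.coords, float)
        if coords.shape != (SNIPPET_LEN, 3):
            raise ValueError(f"snippet must have {SNIPPET_LEN} residues")
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any((d < 2.5) | (d > 4.5)):
            raise ValueError("snippet consecutive distances outside [2.5, 4.5] A")
        object.__setattr__(self, "coords", coords)

    def internal(self) -> InternalCoords:
        return to_internal(self.coords)


class SnippetLibrary:
    """Mapping from target window start position to candidate snippets."""

    def __init__(self, snippets_by_pos: dict | None = None):
        self._by_pos: dict[int, list] = {}
        if snippets_by_pos:
            for pos, snips in snippets_by_pos.items():
                for s in snips:
                    self.add(s)

    def add(self, snippet: Snippet) -> None:
        if snippet.target_pos < 0:
            raise ValueError("negative target position")
        self._by_pos.setdefault(snippet.target_pos, []).append(snippet)

    @property
    def positions(self) -> list:
        return sorted(self._by_pos)

    def snippets_at(self, pos: int) -> list:
        return self._by_pos[pos]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pos.values())

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for pos in self.positions:
                for s in self._by_pos[pos]:
                    fh.write(json.dumps({
                        "target_pos": s.target_pos,
                        "source": s.source,
                        "coords": s.coords.tolist(),
                    }) + "\n")

    @classmethod
    def load_jsonl(cls, path) -> "SnippetLibrary":
        lib = cls()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    d = json.loads(line)
                    lib.add(Snippet(np.array(d["coords"]), d["source"], d["target_pos"]))
        return lib


def build_snippet_library(
    target_length: int,
    alignment_map,
    templates: dict,
) -> SnippetLibrary:
    """Build a library from template traces and a target↔template alignment.

    ``alignment_map`` is an iterable of (target_pos, template_id,
    template_pos) rows; each row contributes the 9-residue template fragment
    starting at ``template_pos``, keyed at ``target_pos``.  Rows without room
    for 9 consecutive template residues, or whose target window overruns the
    target, are skipped (counted in the log).
    """
    if target_length < SNIPPET_LEN:
        raise ValueError(f"target shorter than the {SNIPPET_LEN}-residue window")
    lib = SnippetLibrary()
    skipped = 0
    for target_pos, template_id, template_pos in alignment_map:
        if template_id not in templates:
            raise KeyError(f"unknown template id {template_id!r}")
        tmpl = templates[template_id]
        coords = tmpl.coords if isinstance(tmpl, CaTrace) else np.asarray(tmpl, float)
        if template_pos < 0 or template_pos + SNIPPET_LEN > len(coords):
            skipped += 1
            continue
        if target_pos < 0 or target_pos + SNIPPET_LEN > target_length:
            skipped += 1
            continue
        lib.add(Snippet(
            coords[template_pos : template_pos + SNIPPET_LEN].copy(),
            source=f"{template_id}:{template_pos}",
            target_pos=target_pos,
        ))
    if skipped:
        logger.info("snippet library: skipped %d alignment rows without room", skipped)
    return lib


@dataclass
class AnnealParams:
    """Tunables of one annealing run.

    T0 defaults to L/10 pseudo-energy units at run time (the energy scale is
    O(L)); ``steps`` insertion attempts with quadratic cooling to T_FLOOR.
    """

    steps: int = 3500
    T0: float | None = None
    clash_threshold: float = CLASH_THRESHOLD
    clash_weight: float = 1.0
    coil_bias: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not 0.0 <= self.coil_bias <= 1.0:
            raise ValueError("coil_bias must lie in [0, 1]")


def pick_insertion_site(trace: CaTrace, library: SnippetLibrary, rng,
                        coil_bias: float = 0.8):
    """Pick a (position, snippet): with probability ``coil_bias`` uniformly
    among library positions predicted coil, else uniformly among all library
    positions; uniform among snippets within the position.  Falls back to
    uniform-over-all when no coil position exists."""
    positions = library.positions
    if not positions:
        raise ValueError("empty snippet library")
    if trace.ss3 is None:
        raise ValueError("trace needs ss3 features for coil-biased site selection")
    coil_positions = [p for p in positions if trace.ss3[p] == "C"]
    pool = positions
    if coil_positions and rng.random() < coil_bias:
        pool = coil_positions
    pos = pool[rng.integers(len(pool))]
    snips = library.snippets_at(pos)
    return pos, snips[rng.integers(len(snips))]


def insert_snippet(trace: CaTrace, snippet: Snippet, i: int) -> CaTrace:
    """Replace the internal geometry of window [i, i+9) with the snippet's.

    The splice edits only the window-internal virtual bonds, angles and
    torsions; junction terms and everything outside the window keep the
    current model's values, so upstream residues are unchanged and the
    downstream segment moves as a rigid body.  The input trace is not
    mutated.
    """
    L = len(trace)
    if i < 0 or i + SNIPPET_LEN > L:
        raise ValueError(f"window [{i}, {i + SNIPPET_LEN}) overflows chain of length {L}")
    ic = to_internal(trace.coords)
    sic = snippet.internal()
    new = ic.copy()
    # window residues i..i+8 fully contain bonds i..i+7, angles i..i+6,
    # torsions i..i+5 (index k involves residues k..k+1 / k+2 / k+3)
    new.bond_lengths[i : i + SNIPPET_LEN - 1] = sic.bond_lengths
    new.bond_angles[i : i + SNIPPET_LEN - 2] = sic.bond_angles
    if len(sic.torsions):
        new.torsions[i : i + SNIPPET_LEN - 3] = sic.torsions
    anchor = anchor_from_frame(new, trace.coords)
    coords = from_internal(new, anchor, check_anchor=False)
    return trace.with_coords(coords)


def clash_penalty(trace: CaTrace | np.ndarray, threshold: float = CLASH_THRESHOLD,
                  weight: float = 1.0) -> float:
    """weight × number of residue pairs with |i−j| ≥ 2 closer than
    ``threshold`` Å (bonded neighbours are exempt)."""
    coords = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, float)
    L = len(coords)
    if L < 3:
        return 0.0
    d = pdist(coords)
    i, j = np.triu_indices(L, k=1)
    count = int(np.sum((d < threshold) & (j - i >= 2)))
    return weight * count


def energy(O: float, length: int, clash: float) -> float:
    """Pseudo-energy P_E = L − L·O01 + C with O01 = (O + 1)/2 mapping the
    network output from [−1, 1] onto [0, 1]."""
    o01 = (O + 1.0) / 2.0
    return length - length * o01 + clash


def metropolis_accept(e_cur: float, e_new: float, T: float, rng) -> bool:
    """Standard Metropolis rule: downhill (or equal) moves always accepted,
    uphill moves with probability exp(−(e_new − e_cur)/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if e_new <= e_cur:
        return True
    return rng.random() < np.exp(-(e_new - e_cur) / T)


def temperature(step: int, total_steps: int, T0: float, floor: float = T_FLOOR) -> float:
    """Quadratic cooling: T = max(T0·(1 − step/total)², floor)."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    if total_steps == 0:
        return max(T0, floor)
    frac = 1.0 - step / total_steps
    return max(T0 * frac * frac, floor)


@dataclass
class Trajectory:
    """Bookkeeping of one annealing run.

    Stores per-step energies/acceptance flags and the coordinates at every
    accepted step, so the conformation at any step can be replayed.
    """

    start_coords: np.ndarray
    energies: list = field(default_factory=list)   # current energy after each step
    accepted: list = field(default_factory=list)   # bool per step
    snapshots: dict = field(default_factory=dict)  # step -> coords (accepted states)
    initial_energy: float = float("nan")

    @property
    def n_steps(self) -> int:
        return len(self.energies)

    @property
    def n_accepted(self) -> int:
        return int(np.sum(self.accepted))

    def coords_at(self, step: int) -> np.ndarray:
        """Coordinates of the current model after ``step`` steps (1-based;
        step 0 is the start)."""
        best = None
        for s in self.snapshots:
            if s <= step and (best is None or s > best):
                best = s
        return self.start_coords if best is None else self.snapshots[best]

    def changed_between(self, a: int, b: int) -> bool:
        """True if any move was accepted in (a, b]."""
        return any(a < s <= b for s in self.snapshots)


def reconstruct(
    start: CaTrace,
    library: SnippetLibrary,
    model: NNPIFModel,
    params: AnnealParams,
    score_fn=None,
) -> tuple[CaTrace, Trajectory]:
    """Run the annealing search from ``start``; returns the final model and
    the trajectory.

    ``score_fn(coords) -> O`` may replace the network (e.g. an oracle in
    tests); by default each candidate is encoded and scored by ``model``.
    Fully reproducible given ``params.seed``.
    """
    if start.ss3 is None:
        raise ValueError("start trace needs ss3 features")
    rng = np.random.default_rng(params.seed)
    L = len(start)
    T0 = params.T0 if params.T0 is not None else max(L / 10.0, 10 * T_FLOOR)

    encoder = ConformationEncoder(start) if score_fn is None else None

    def score(coords) -> float:
        if score_fn is not None:
            return float(score_fn(coords))
        enc = encode_conformation(start, encoder=encoder, coords=coords)
        return forward(model, enc)[0]

    current = start.copy()
    cur_O = score(current.coords)
    cur_E = energy(cur_O, L, clash_penalty(current.coords, params.clash_threshold,
                                           params.clash_weight))
    traj = Trajectory(start_coords=start.coords.copy(), initial_energy=cur_E)
    for step in range(1, params.steps + 1):
        T = temperature(step - 1, params.steps, T0)
        pos, snip = pick_insertion_site(current, library, rng, params.coil_bias)
        cand = insert_snippet(current, snip, pos)
        if not np.all(np.isfinite(cand.coords)):
            traj.energies.append(cur_E)
            traj.accepted.append(False)
            continue
        new_O = score(cand.coords)
        new_E = energy(new_O, L, clash_penalty(cand.coords, params.clash_threshold,
                                               params.clash_weight))
        if metropolis_accept(cur_E, new_E, T, rng):
            current, cur_E = cand, new_E
            traj.snapshots[step] = cand.coords.copy()
            traj.accepted.append(True)
        else:
            traj.accepted.append(False)
        traj.energies.append(cur_E)
    return current, traj
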