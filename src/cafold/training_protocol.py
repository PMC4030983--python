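"""Iterative decoy-set construction and phase-wise training.

The scorer is trained on (conformation, quality) decoys harvested from its
own search pathways.  The decoy set starts from the native structures
(q = +1); before every phase — including the first, where the network still
has its random initial weights — every training target is reconstructed
twice with the current network, once starting from the native ("backward")
and once from a random extended chain ("forward"), and up to 50 snapshots
per trajectory, at an interval drawn from {10, 50, 100} steps, are labelled
against the native and merged in after duplicate removal.  Phase p trains
for 50·p epochs at a learning rate of 0.5 divided by the *initial*
(first-phase) training-set size, never updated as the set grows, batch
size 2.  Held-out targets supply the test decoys: generated by the same
current network but never trained on, evaluated every 10 epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoding import ConformationEncoder, encode_conformation
from .metrics import contact_quality
from .nnpif import NNPIFModel, evaluate_error, train_epochs
from .reconstructor import AnnealParams, Trajectory, reconstruct
from .structures import CaTrace, random_extended_trace

logger = logging.getLogger(__name__)

SAMPLE_INTERVALS = (10, 50, 100)
MAX_SAMPLES = 50
FINGERPRINT_DECIMALS = 2  # coordinates rounded to 0.01 A


@dataclass
class Decoy:
    """One labelled conformation with provenance."""

    trace: CaTrace
    q: float
    target_id: str
    phase: int
    kind: str  # backward | forward | native
    step: int = 0
    encoding: object = None  # lazily attached pair encodings

    def __post_init__(self):
        if not -1.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [-1, 1]")
        if self.kind not in ("backward", "forward", "native"):
            raise ValueError(f"unknown reconstruction kind {self.kind!r}")


def fingerprint(target_id: str, coords: np.ndarray) -> tuple:
    """Dedup key: target id + coordinates rounded to 0.01 Å."""
    return (target_id, np.round(np.asarray(coords, float), FINGERPRINT_DECIMALS).tobytes())


class DecoySet:
    """Growing decoy collection with coordinate-fingerprint deduplication."""

    def __init__(self):
        self.decoys: list = []
        self._index: set = set()

    def __len__(self) -> int:
        return len(self.decoys)

    def __iter__(self):
        return iter(self.decoys)

    def add(self, decoy: Decoy) -> bool:
        fp = fingerprint(decoy.target_id, decoy.trace.coords)
        if fp in self._index:
            return False
        self._index.add(fp)
        self.decoys.append(decoy)
        return True


def dedup_merge(decoy_set: DecoySet, new_decoys) -> DecoySet:
    """Merge ``new_decoys`` into ``decoy_set`` in order, dropping fingerprint
    duplicates; mutates and returns the set."""
    new_decoys = list(new_decoys)
    added = sum(decoy_set.add(d) for d in new_decoys)
    logger.info("dedup_merge: kept %d of %d new decoys (set size %d)",
                added, len(new_decoys), len(decoy_set))
    return decoy_set


def sample_trajectory(
    trajectory: Trajectory,
    native: CaTrace,
    interval: int,
    target_id: str,
    phase: int,
    kind: str,
    max_samples: int = MAX_SAMPLES,
) -> list:
    """Snapshots at steps interval, 2·interval, … (≤ ``max_samples``),
    labelled against the native; a snapshot at which the model has not
    changed since the previously retained one is dropped."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    decoys = []
    last_retained_step = 0
    first = True
    step = interval
    while step <= trajectory.n_steps and len(decoys) < max_samples:
        if first or trajectory.changed_between(last_retained_step, step):
            coords = trajectory.coords_at(step)
            trace = native.with_coords(coords.copy())
            q = contact_quality(trace, native)
            if q is not None:
                decoys.append(Decoy(trace, q, target_id, phase, kind, step))
            first = False
            last_retained_step = step
        step += interval
    return decoys


def run_round(targets, model: NNPIFModel, params: AnnealParams, phase: int,
              rng=None) -> list:
    """One decoy-harvest round: per target a backward (from the native) and a
    forward (from a random extended chain) reconstruction, each sampled at an
    interval drawn per-reconstruction from {10, 50, 100}."""
    rng = np.random.default_rng(rng)
    decoys = []
    for target in targets:
        native = target.native
        for kind in ("backward", "forward"):
            if kind == "backward":
                start = native.copy()
            else:
                start = random_extended_trace(native.sequence, rng.integers(2**31))
                start = CaTrace(native.sequence, start.coords, native.ss3, native.acc)
            run_params = AnnealParams(
                steps=params.steps, T0=params.T0,
                clash_threshold=params.clash_threshold,
                clash_weight=params.clash_weight,
                coil_bias=params.coil_bias,
                seed=int(rng.integers(2**31)),
            )
            _, traj = reconstruct(start, target.library, model, run_params)
            interval = int(rng.choice(SAMPLE_INTERVALS))
            decoys.extend(sample_trajectory(
                traj, native, interval, target.target_id, phase, kind,
            ))
    return decoys


def _ensure_encoding(decoy: Decoy, encoders: dict) -> None:
    if decoy.encoding is None:
        enc = encoders.get(decoy.target_id)
        if enc is None:
            enc = encoders[decoy.target_id] = ConformationEncoder(decoy.trace)
        decoy.encoding = encode_conformation(decoy.trace, encoder=enc)


def _examples(decoy_set, encoders: dict) -> list:
    out = []
    for d in decoy_set:
        _ensure_encoding(d, encoders)
        out.append((d.encoding, d.q))
    return out


@dataclass
class TrainingHistory:
    """Per-epoch error history across phases."""

    records: list = field(default_factory=list)  # (phase, epoch, train_mse, test_mse|None)

    def add(self, phase, epoch, train_mse, test_mse=None):
        self.records.append((phase, epoch, train_mse, test_mse))

    def train_errors(self, phase=None):
        return [r[2] for r in self.records if phase is None or r[0] == phase]

    def test_errors(self):
        return [(r[0], r[1], r[3]) for r in self.records if r[3] is not None]

    def save_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("phase\tepoch\ttrain_mse\ttest_mse\n")
            for p, e, tr, te in self.records:
                fh.write(f"{p}\t{e}\t{tr:.8g}\t{'' if te is None else f'{te:.8g}'}\n")


def iterative_train(
    targets,
    phases: int,
    model: NNPIFModel,
    anneal_params: AnnealParams,
    seed: int = 0,
    test_fraction: float = 0.3,
    epochs_per_phase: int = 50,
    lr_numerator: float = 0.5,
    batch: int = 2,
    test_every: int = 10,
    keep_phase_models: bool = False,
):
    """Phase-wise training with iterative decoy-set expansion.

    Targets are split into train/held-out partitions; the held-out targets
    provide test decoys generated by the current network each phase but never
    trained on.  Phase p runs ``epochs_per_phase``·p epochs.  The learning
    rate is ``lr_numerator`` / (first-phase training-set size: natives plus
    the initial harvest round) and is kept fixed across phases.  Returns
    (trained model, history, final decoy set) — plus the per-phase model
    snapshots and the test example list when ``keep_phase_models`` is set.
    """
    targets = list(targets)
    if phases < 1:
        raise ValueError("phases must be >= 1")
    if not targets:
        raise ValueError("no targets")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(targets)))) if len(targets) > 1 else 0
    train_targets = targets[: len(targets) - n_test]
    test_targets = targets[len(targets) - n_test :]
    if not train_targets:
        train_targets, test_targets = targets, []

    encoders: dict = {}
    decoy_set = DecoySet()
    for t in train_targets:
        decoy_set.add(Decoy(t.native.copy(), 1.0, t.target_id, 0, "native"))
    test_set = DecoySet()
    for t in test_targets:
        test_set.add(Decoy(t.native.copy(), 1.0, t.target_id, 0, "native"))

    lr = None
    history = TrainingHistory()
    phase_models = []
    epoch_global = 0
    for phase in range(1, phases + 1):
        new = run_round(train_targets, model, anneal_params, phase,
                        rng=rng.integers(2**31))
        dedup_merge(decoy_set, new)
        if test_targets:
            new_test = run_round(test_targets, model, anneal_params, phase,
                                 rng=rng.integers(2**31))
            dedup_merge(test_set, new_test)
        if lr is None:  # fixed from the first-phase set size onwards
            lr = lr_numerator / len(decoy_set)
        examples = _examples(decoy_set, encoders)
        test_examples = _examples(test_set, encoders) if len(test_set) else None
        if phase == 1:
            # epoch-0 point of the error curves (recorded as phase 0):
            # the untrained network before any gradient step
            history.add(0, 0, evaluate_error(model, examples),
                        evaluate_error(model, test_examples)
                        if test_examples else None)
        n_epochs = epochs_per_phase * phase
        logger.info("phase %d: %d decoys, %d epochs, lr %.3g",
                    phase, len(examples), n_epochs, lr)
        for chunk_start in range(0, n_epochs, test_every):
            chunk = min(test_every, n_epochs - chunk_start)
            model, errs = train_epochs(
                model, examples, lr=lr, batch=batch, epochs=chunk,
                seed=int(rng.integers(2**31)),
            )
            for k, e in enumerate(errs):
                epoch_global += 1
                is_last = k == len(errs) - 1
                test_mse = (
                    evaluate_error(model, test_examples)
                    if is_last and test_examples else None
                )
                history.add(phase, epoch_global, e, test_mse)
        if keep_phase_models:
            phase_models.append(model.copy())
    if keep_phase_models:
        return model, history, decoy_set, phase_models, test_examples
    return model, history, decoy_set
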