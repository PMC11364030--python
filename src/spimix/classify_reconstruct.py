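"""Threshold classification, per-class 3D merging and the outer iteration
loop of the one-step classification–multireconstruction algorithm.

Each iteration: slice the current templates at every grid orientation,
compute CC_max(n, m) for every pattern/template pair, classify each pattern
to its best template only when the top-two margin CC¹_max − CC²_max exceeds
the rejection threshold (otherwise it stays unclassified for this round),
then merge each class's patterns — at their best orientations — into a new
3D intensity that replaces the template.  All patterns are re-evaluated
every iteration, so early misclassifications can be corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import IntensityVolume, PatternSet, RunConfig
from .match import CCTable, compute_cc_table
from .orientations import euler_to_matrix, sample_grid
from .simulate import DetectorGeometry, ewald_map
from .templates import downsample_pattern, downsample_volume, friedel_symmetrize

__all__ = [
    "UNCLASSIFIED",
    "Assignment",
    "IterationState",
    "assign_classes",
    "merge_patterns",
    "run",
]

#: label given to patterns whose top-two CC margin is below threshold
UNCLASSIFIED = -1


@dataclass
class Assignment:
    """Per-pattern class (or :data:`UNCLASSIFIED`), best orientation of the
    winning class and the winning CC value."""

    labels: np.ndarray    # (N,) int
    euler: np.ndarray     # (N, 3) float
    cc: np.ndarray        # (N,) float

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_unclassified(self) -> int:
        return int(np.sum(self.labels == UNCLASSIFIED))

    def class_counts(self, n_classes: int) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0], minlength=n_classes)


@dataclass
class IterationState:
    """State after one iteration of the loop."""

    iteration: int
    templates: list[IntensityVolume]
    assignment: Assignment
    summary: dict = field(default_factory=dict)


def assign_classes(cc_table: CCTable, threshold: float) -> Assignment:
    """Classify each pattern by its sorted CC_max values.

    A pattern goes to the argmax class iff CC¹_max − CC²_max > threshold
    (strict); otherwise it is unclassified.  A single-template table is
    degenerate: everything goes to class 0.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cc = cc_table.cc
    n, m = cc.shape
    if m == 1:
        labels = np.zeros(n, dtype=int)
    else:
        order = np.argsort(cc, axis=1)
        top1 = cc[np.arange(n), order[:, -1]]
        top2 = cc[np.arange(n), order[:, -2]]
        margin = top1 - top2
        ok = np.isfinite(top1) & (margin > threshold)
        labels = np.where(ok, np.argmax(cc, axis=1), UNCLASSIFIED)
    idx = np.maximum(labels, 0)
    rows = np.arange(n)
    return Assignment(labels=labels,
                      euler=cc_table.euler[rows, idx].copy(),
                      cc=cc[rows, idx].copy())


def merge_patterns(patterns: PatternSet, assignment: Assignment,
                   geometry: DetectorGeometry, dq: float, grid_n: int,
                   n_classes: int,
                   fluence_correction: bool = False
                   ) -> list[IntensityVolume | None]:
    """Merge each class's patterns into a 3D intensity volume.

    Every classified pattern's Ewald q-points are rotated by its best
    orientation and its photon counts scattered into the voxel grid with
    trilinear weights; voxel values are the weighted mean of deposited
    counts, Friedel-symmetrized.  Voxels never touched are 0 and flagged
    missing.  Classes with no patterns yield ``None`` (the caller keeps the
    previous template).  ``fluence_correction`` optionally rescales each
    pattern by its recorded relative fluence before merging (off by
    default: the reference algorithm applies no such correction, and
    Pearson matching is scale-invariant).
    """
    ew = ewald_map(geometry)
    det_mask = patterns.mask & geometry.valid_mask()
    q_flat = ew.q.reshape(-1, 3)
    sel_px = det_mask.ravel()
    half = grid_n // 2

    out: list[IntensityVolume | None] = []
    for cls in range(n_classes):
        members = np.where(assignment.labels == cls)[0]
        if len(members) == 0:
            out.append(None)
            continue
        acc = np.zeros((grid_n,) * 3)
        wt = np.zeros((grid_n,) * 3)
        for i in members:
            rot = euler_to_matrix(*assignment.euler[i])
            coords = (q_flat[sel_px] @ rot.T) / dq + half
            vals = patterns.patterns[i].astype(float).ravel()[sel_px]
            if fluence_correction:
                vals = vals * (patterns.fluence.mean() / patterns.fluence[i])
            _deposit_trilinear(acc, wt, coords, vals)
        vol = IntensityVolume(np.where(wt > 0, acc / np.maximum(wt, 1e-300), 0.0),
                              dq, missing=wt <= 0)
        out.append(friedel_symmetrize(vol))
    return out


def _deposit_trilinear(acc: np.ndarray, wt: np.ndarray,
                       coords: np.ndarray, vals: np.ndarray) -> None:
    """Scatter ``vals`` at fractional ``coords`` (n, 3) into acc/wt."""
    n = acc.shape[0]
    i0 = np.floor(coords).astype(int)
    frac = coords - i0
    flats, wts = [], []
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + off
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        inb = np.all((idx >= 0) & (idx < n), axis=1) & (w > 0)
        if not inb.any():
            continue
        flats.append(np.ravel_multi_index(tuple(idx[inb].T), (n, n, n)))
        wts.append((w[inb], vals[inb]))
    if not flats:
        return
    flat = np.concatenate(flats)
    w_all = np.concatenate([w for w, _ in wts])
    wv_all = np.concatenate([w * v for w, v in wts])
    size = n ** 3
    acc.ravel()[:] += np.bincount(flat, weights=wv_all, minlength=size)
    wt.ravel()[:] += np.bincount(flat, weights=w_all, minlength=size)


def run(patterns: PatternSet, initial_templates: list[IntensityVolume],
        config: RunConfig,
        thresholds: list[float] | None = None
        ) -> tuple[IterationState, list[IterationState]]:
    """The full iterative loop on raw (full-resolution) inputs.

    Patterns and templates are first downsampled 2× (sum-binned counts,
    mean-binned volumes).  Then, until assignments stabilize (fraction of
    patterns whose class or orientation changed < ``config.stop_tol``) or
    ``config.max_iterations`` is hit: match → classify → merge → replace
    templates.  ``thresholds`` optionally overrides the CC threshold per
    iteration (e.g. a decaying schedule); by default the fixed
    ``config.cc_threshold`` is used throughout.

    Returns the final state and the per-iteration history (the history
    entries carry full assignments for trajectory-style evaluation).
    """
    geom = DetectorGeometry.from_config(config).downsampled(2)
    counts, mask = downsample_pattern(patterns.patterns, patterns.mask, 2)
    ps = PatternSet(patterns=counts, mask=mask, species=patterns.species,
                    euler=patterns.euler, fluence=patterns.fluence)
    templates = [downsample_volume(t, 2) for t in initial_templates]
    n_classes = len(templates)
    if n_classes < 1:
        raise ValueError("at least one template is required")
    dq = templates[0].dq
    grid_n = templates[0].n
    grid = sample_grid(np.deg2rad(config.angular_step_deg))

    history: list[IterationState] = []
    prev: Assignment | None = None
    state = None
    for it in range(1, config.max_iterations + 1):
        table = compute_cc_table(ps, templates, grid, geom,
                                 n_theta=config.n_theta, dtype=np.float32)
        thr = (thresholds[min(it - 1, len(thresholds) - 1)]
               if thresholds else config.cc_threshold)
        assignment = assign_classes(table, thr)
        if assignment.n_unclassified == len(ps):
            raise RuntimeError(
                "all patterns unclassified; the threshold is too strict or "
                "the templates are too poor for this data")
        if prev is None:
            frac_changed = 1.0
        else:
            changed = (assignment.labels != prev.labels) | \
                np.any(assignment.euler != prev.euler, axis=1)
            frac_changed = float(changed.mean())
        merged = merge_patterns(ps, assignment, geom, dq, grid_n, n_classes)
        templates = [new if new is not None else old
                     for new, old in zip(merged, templates)]
        cls_counts = assignment.class_counts(n_classes)
        state = IterationState(
            iteration=it, templates=templates, assignment=assignment,
            summary={
                "iteration": it,
                "class_counts": cls_counts.tolist(),
                "n_unclassified": assignment.n_unclassified,
                "frac_changed": frac_changed,
                "mean_cc": float(np.mean(assignment.cc[assignment.labels >= 0])),
                "threshold": thr,
            })
        history.append(state)
        prev = assignment
        if frac_changed < config.stop_tol:
            break
    return state, history
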