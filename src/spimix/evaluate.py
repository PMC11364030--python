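"""Resolution and accuracy metrics: shell correlation between volumes,
classification confusion/accuracy trajectories and orientation errors.

These metrics consume the simulation's hidden ground truth (species labels,
orientations, true intensity volumes); the classification algorithm itself
never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify_reconstruct import UNCLASSIFIED, Assignment
from .io_formats import IntensityVolume
from .orientations import euler_to_matrix, geodesic_distance

__all__ = [
    "ShellCCCurve",
    "ConfusionSummary",
    "shell_cc",
    "confusion",
    "orientation_error",
]


@dataclass
class ShellCCCurve:
    """Per-resolution-shell Pearson CC between two volumes.

    ``resolution_A`` is d = 1/|q| at the first (linearly interpolated)
    crossing of CC below 0.5; NaN if the curve never drops below 0.5 in the
    measured range (resolution limited by the detector edge) or starts
    below it.
    """

    q_centers: np.ndarray       # (S,) shell centres, Å⁻¹
    cc: np.ndarray              # (S,) Pearson CC (NaN where undefined)
    resolution_A: float

    @property
    def d_centers(self) -> np.ndarray:
        """Shell centres as resolution d = 1/|q|, Å."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.q_centers


def _resolution_at(q: np.ndarray, cc: np.ndarray, level: float = 0.5) -> float:
    """d = 1/q at the first crossing of ``cc`` below ``level``.

    The search starts at the first shell at or above the level: shells
    bordering the central hole (beam stop) are sparsely covered and can sit
    low without meaning loss of resolution.  NaN if the curve never reaches
    the level, or never drops below it in the measured range (resolution
    limited by the detector edge).
    """
    ok = np.isfinite(cc)
    q, cc = q[ok], cc[ok]
    above = np.where(cc >= level)[0]
    if len(above) == 0:
        return float("nan")
    start = above[0]
    below = start + np.where(cc[start:] < level)[0]
    if len(below) == 0:
        return float("nan")
    j = below[0]
    q0, q1 = q[j - 1], q[j]
    c0, c1 = cc[j - 1], cc[j]
    qc = q0 + (c0 - level) / (c0 - c1) * (q1 - q0)
    return float(1.0 / qc)


def shell_cc(vol_a: IntensityVolume, vol_b: IntensityVolume,
             n_shells: int = 50, min_pairs: int = 10) -> ShellCCCurve:
    """Pearson CC between two volumes within spherical resolution shells.

    Shells are contiguous over [0, q_max] (q_max = half-width of the grid);
    voxels flagged missing in either volume are excluded pairwise; shells
    with fewer than ``min_pairs`` valid pairs report NaN.
    """
    if vol_a.n != vol_b.n or not np.isclose(vol_a.dq, vol_b.dq):
        raise ValueError("volumes must share grid size and spacing")
    n = vol_a.n
    half = n // 2
    ax = np.arange(n) - half
    qlen = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 +
                   ax[None, None, :] ** 2) * vol_a.dq
    q_max = half * vol_a.dq
    edges = np.linspace(0.0, q_max, n_shells + 1)
    shell_idx = np.clip(np.searchsorted(edges, qlen, side="right") - 1,
                        0, n_shells - 1)
    valid = (qlen <= q_max) & vol_a.valid_mask() & vol_b.valid_mask()

    centers = 0.5 * (edges[:-1] + edges[1:])
    ccs = np.full(n_shells, np.nan)
    flat_idx = shell_idx[valid]
    a = vol_a.data[valid]
    b = vol_b.data[valid]
    for s in range(n_shells):
        sel = flat_idx == s
        if sel.sum() < min_pairs:
            continue
        xa, xb = a[sel], b[sel]
        da, db = xa - xa.mean(), xb - xb.mean()
        denom = np.sqrt((da @ da) * (db @ db))
        if denom > 0:
            ccs[s] = float((da @ db) / denom)
    return ShellCCCurve(q_centers=centers, cc=ccs,
                        resolution_A=_resolution_at(centers, ccs))


@dataclass
class ConfusionSummary:
    """K×(K+1) confusion matrix (true species × assigned class, last column
    unclassified) and the accuracy over successfully classified patterns."""

    matrix: np.ndarray          # (K, K+1) int
    accuracy: float             # correct / classified, NaN if none classified

    @property
    def n_unclassified(self) -> int:
        return int(self.matrix[:, -1].sum())


def confusion(assignments: Assignment | list[Assignment],
              truth_labels: np.ndarray,
              n_classes: int | None = None
              ) -> ConfusionSummary | list[ConfusionSummary]:
    """Confusion summaries for one assignment or a per-iteration history.

    Accuracy is (correctly classified) / (successfully classified) —
    unclassified patterns are excluded from the denominator.
    """
    if isinstance(assignments, list):
        return [confusion(a, truth_labels, n_classes) for a in assignments]
    a = assignments
    truth = np.asarray(truth_labels, dtype=int)
    if len(a) != len(truth):
        raise ValueError("assignment/truth length mismatch")
    k = int(n_classes if n_classes is not None else truth.max() + 1)
    mat = np.zeros((k, k + 1), dtype=int)
    cols = np.where(a.labels == UNCLASSIFIED, k, a.labels)
    np.add.at(mat, (truth, cols), 1)
    classified = mat[:, :k].sum()
    correct = np.trace(mat[:, :k])
    acc = float(correct / classified) if classified > 0 else float("nan")
    return ConfusionSummary(matrix=mat, accuracy=acc)


def orientation_error(assignment: Assignment,
                      truth_euler: np.ndarray,
                      classified_only: bool = True) -> np.ndarray:
    """Per-pattern geodesic SO(3) distance (radians) between assigned and
    true orientations, minimized over the Friedel-equivalent mate
    (R ~ R·Rz(π): intensities cannot distinguish the pair).

    With ``classified_only`` (default) unclassified patterns get NaN.
    """
    truth_euler = np.asarray(truth_euler, float)
    out = np.full(len(assignment), np.nan)
    for i in range(len(assignment)):
        if classified_only and assignment.labels[i] == UNCLASSIFIED:
            continue
        r_est = euler_to_matrix(*assignment.euler[i])
        r_true = euler_to_matrix(*truth_euler[i])
        out[i] = geodesic_distance(r_true, r_est, friedel=True)
    return out
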