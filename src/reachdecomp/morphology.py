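"""Morphology of movement-element velocity profiles.

Profiles are spatially normalized (divided by their mean speed, after
sign-flipping negative lobes) and temporally normalized (linearly
resampled to 60 samples), then summarized by the first two principal
components of a PCA fit in a leave-one-subject-out manner so a
participant's own profiles never shape the basis used to score them.
The reference profile for the within-task optimization analysis is the
minimum-jerk speed curve s(tau) = 30 tau^2 (1 - tau)^2 (unit mean on
[0, 1]), the theoretical optimum for point-to-point reaches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

N_SHAPE_SAMPLES = 60


@dataclass
class LosoPCA:
    """A PCA basis fit with one participant held out."""

    mean: np.ndarray  # (60,)
    components: np.ndarray  # (2, 60), rows orthonormal
    explained_variance: np.ndarray
    held_out: object

    def transform(self, shapes: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(shapes) - self.mean) @ self.components.T


def normalize_element(profile: np.ndarray, n: int = N_SHAPE_SAMPLES) -> np.ndarray:
    """Unit-mean, n-sample shape of one element's velocity profile.

    Negative lobes are sign-flipped first; the mean is re-normalized to
    exactly 1 after resampling.
    """
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise ValueError("empty profile")
    if np.mean(p) < 0:
        p = -p
    m = np.mean(p)
    if m == 0:
        raise ValueError("zero mean speed: cannot normalize")
    p = p / m
    if p.size == 1:
        shape = np.full(n, p[0])
    else:
        tau = np.linspace(0.0, 1.0, p.size)
        shape = np.interp(np.linspace(0.0, 1.0, n), tau, p)
    return shape / np.mean(shape)


def hoff_reference(n: int = N_SHAPE_SAMPLES) -> np.ndarray:
    """Minimum-jerk speed profile, sampled at n points, unit mean."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    tau = np.linspace(0.0, 1.0, n)
    s = 30.0 * tau**2 * (1.0 - tau) ** 2
    return s / np.mean(s)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    # reproducibility convention: each loading's largest-|.| coordinate > 0
    out = components.copy()
    for i, c in enumerate(out):
        if c[np.argmax(np.abs(c))] < 0:
            out[i] = -c
    return out


def _pca_from_scatter(
    total: np.ndarray, scatter: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-2 PCA from summed vectors/outer-products of n training profiles."""
    mean = total / n
    cov = (scatter - n * np.outer(mean, mean)) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:2]
    if eigvals[order[1]] <= 1e-14:
        raise ValueError("training profiles have rank < 2")
    components = _fix_signs(eigvecs[:, order].T)
    return mean, components, eigvals[order]


def loso_pca(profiles_by_participant: dict, held_out) -> tuple[LosoPCA, np.ndarray]:
    """Fit a 2-component PCA on all participants except ``held_out``.

    Returns the basis and the held-out participant's scores.
    """
    train_ids = [p for p in profiles_by_participant if p != held_out]
    if len(train_ids) < 2:
        raise ValueError("need at least 2 training participants")
    rows = [np.atleast_2d(profiles_by_participant[p]) for p in train_ids]
    x = np.vstack(rows)
    mean, components, ev = _pca_from_scatter(x.sum(axis=0), x.T @ x, x.shape[0])
    basis = LosoPCA(mean=mean, components=components, explained_variance=ev,
                    held_out=held_out)
    scores = basis.transform(np.atleast_2d(profiles_by_participant[held_out]))
    return basis, scores


def loso_scores(profiles_by_participant: dict) -> dict:
    """LOSO PC scores for every participant.

    Uses cached per-participant sums so each fold's covariance is the
    total minus the held-out contribution (exactly equivalent to
    refitting PCA on the training profiles).
    """
    ids = list(profiles_by_participant)
    mats = {p: np.atleast_2d(np.asarray(profiles_by_participant[p], dtype=float))
            for p in ids}
    sums = {p: mats[p].sum(axis=0) for p in ids}
    scatters = {p: mats[p].T @ mats[p] for p in ids}
    counts = {p: mats[p].shape[0] for p in ids}
    total_sum = np.sum([sums[p] for p in ids], axis=0)
    total_scatter = np.sum([scatters[p] for p in ids], axis=0)
    n_total = sum(counts.values())

    out = {}
    for p in ids:
        n_train = n_total - counts[p]
        mean, components, ev = _pca_from_scatter(
            total_sum - sums[p], total_scatter - scatters[p], n_train
        )
        out[p] = (mats[p] - mean) @ components.T
    return out


def profile_r2(shape: np.ndarray, reference: np.ndarray) -> float:
    """Coefficient of determination of a shape against the reference."""
    ss_res = float(np.sum((shape - reference) ** 2))
    ss_tot = float(np.sum((shape - np.mean(shape)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class HalfTestResult:
    deltas: pd.DataFrame  # per participant-hand: delta_sd_pc1/pc2, delta_r2_hoff
    tests: dict  # metric -> (t, p), one-sample t against 0


def half_test_comparison(
    per_hand: dict,
    hoff: np.ndarray | None = None,
    half_time_s: float = 20.0,
    min_per_half: int = 2,
) -> HalfTestResult:
    """Within-task morphology change, first vs second half of the task.

    ``per_hand`` maps (participant_id, hand) to a tuple
    ``(start_times, shapes, pc_scores)`` with shapes of width 60 and pc
    scores of width 2.  For each participant-hand the change
    (second half minus first half) in SD(PC1), SD(PC2), and mean r^2
    against the reference profile is computed; hands with fewer than
    ``min_per_half`` elements in either half are skipped with a warning.
    """
    if hoff is None:
        hoff = hoff_reference()
    rows = []
    for (pid, hand), (times, shapes, scores) in per_hand.items():
        times = np.asarray(times, dtype=float)
        shapes = np.atleast_2d(shapes)
        scores = np.atleast_2d(scores)
        first = times < half_time_s
        second = ~first
        if first.sum() < min_per_half or second.sum() < min_per_half:
            warnings.warn(f"skipping {pid}/{hand}: too few elements in a half")
            continue

        def _sd(mask, col):
            return float(np.std(scores[mask, col], ddof=1))

        def _r2(mask):
            return float(np.mean([profile_r2(s, hoff) for s in shapes[mask]]))

        rows.append(
            dict(
                participant_id=pid,
                hand=hand,
                delta_sd_pc1=_sd(second, 0) - _sd(first, 0),
                delta_sd_pc2=_sd(second, 1) - _sd(first, 1),
                delta_r2_hoff=_r2(second) - _r2(first),
            )
        )
    deltas = pd.DataFrame(rows)
    tests = {}
    for metric in ("delta_sd_pc1", "delta_sd_pc2", "delta_r2_hoff"):
        if len(deltas) >= 2 and np.std(deltas[metric].to_numpy(), ddof=1) > 0:
            t, p = sps.ttest_1samp(deltas[metric].to_numpy(), 0.0)
            tests[metric] = (float(t), float(p))
        elif len(deltas) >= 1 and np.allclose(deltas[metric], 0.0):
            tests[metric] = (0.0, 1.0)
    return HalfTestResult(deltas=deltas, tests=tests)
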