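"""Inverted encoding model: estimation, inversion, recentering, cross-validation.

The forward model is B1 = W C1, where B1 (v voxels × n trials) holds the
voxel patterns, C1 (k channels × n trials) the idealized channel responses
for the training labels, and W (v × k) the voxel selectivity.  Training
solves the least-squares closed form

    What = B1 C1' (C1 C1')^-1

and inversion recovers channel responses on held-out data by

    C2hat = (What' What)^-1 What' B2.

Cross-validated time courses use a leave-one-run-out scheme, training and
testing on the same TR with prioritized-item (PMI) labels, then recentering
each trial's reconstruction so the channel nearest the tested item's
feature sits at the 0°-offset position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import ChannelBasis, ideal_channel_matrix
from .synth import BoldDataset, N_TRS_PER_TRIAL

__all__ = [
    "RankDeficiencyError",
    "estimate_weights",
    "invert_model",
    "recenter_reconstruction",
    "crossval_reconstruct_timecourse",
    "preprocess",
    "Reconstruction",
    "TimecourseReconstruction",
]

# The raised-power channel basis is smooth, so its Gram matrices are
# legitimately ill-conditioned (~1e10 with few voxels); only treat
# conditioning far beyond that as rank deficiency.
_COND_MAX = 1e13


class RankDeficiencyError(np.linalg.LinAlgError):
    """A Gram matrix in the closed-form solution is (near-)singular."""


@dataclass
class Reconstruction:
    """Channel-response estimates, k channels × n trials, for one TR."""

    values: np.ndarray
    basis: ChannelBasis
    recentered: bool = False
    tr_index: int | None = None
    feature_dim: str | None = None
    item: str | None = None

    @property
    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class TimecourseReconstruction:
    """Recentered reconstructions per TR from leave-one-run-out decoding.

    ``per_trial[tr]`` is k × n_trials (trials in design row order);
    ``mean_curves`` stacks the trial averages, one row per requested TR.
    """

    trs: tuple
    per_trial: dict
    basis: ChannelBasis
    feature_dim: str
    item: str
    extras: dict = field(default_factory=dict)

    @property
    def mean_curves(self) -> np.ndarray:
        return np.stack([self.per_trial[tr].mean(axis=1) for tr in self.trs])

    def curve(self, tr: int) -> np.ndarray:
        return self.per_trial[tr].mean(axis=1)

    def to_frame(self, subject=None, roi=None) -> pd.DataFrame:
        """Long-format export: subject, roi, feature_dim, item, tr,
        channel_offset_deg, response (trial-averaged)."""
        rows = []
        offs = self.basis.offsets
        for tr in self.trs:
            curve = self.curve(tr)
            for off, resp in zip(offs, curve):
                rows.append((subject, roi, self.feature_dim, self.item, tr, off, resp))
        return pd.DataFrame(
            rows,
            columns=["subject", "roi", "feature_dim", "item", "tr",
                     "channel_offset_deg", "response"],
        )


def _check_cond(gram: np.ndarray, what: str):
    if not np.all(np.isfinite(gram)):
        raise RankDeficiencyError(f"{what} contains non-finite values")
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise RankDeficiencyError(
            f"{what} is singular or near-singular (condition number {cond:.3g}); "
            "the training labels do not span the channel space"
        )


def estimate_weights(b1: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """Closed-form weight estimate What = B1 C1' (C1 C1')^-1 (v × k)."""
    b1 = np.asarray(b1, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    k, n = c1.shape
    if b1.shape[1] != n:
        raise ValueError("B1 and C1 must have the same number of trials")
    if n < k:
        raise RankDeficiencyError(
            f"need at least k={k} training trials, got n={n}"
        )
    gram = c1 @ c1.T
    _check_cond(gram, "C1 C1^T (channel Gram matrix)")
    return np.linalg.solve(gram.T, (b1 @ c1.T).T).T


def invert_model(w: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Closed-form inversion C2hat = (W'W)^-1 W' B2 (k × n)."""
    w = np.asarray(w, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    v, k = w.shape
    if v < k:
        raise RankDeficiencyError(
            f"underdetermined inversion: {v} voxels < {k} channels"
        )
    if b2.shape[0] != v:
        raise ValueError("B2 voxel dimension does not match the weight matrix")
    gram = w.T @ w
    _check_cond(gram, "W^T W (weight Gram matrix)")
    return np.linalg.solve(gram, w.T @ b2)


def recenter_reconstruction(
    values: np.ndarray, labels, basis: ChannelBasis
) -> np.ndarray:
    """Circularly shift each trial's k-vector so the channel nearest its
    label lands at the basis's 0°-offset position.

    A pure per-column permutation: sums and value multisets are preserved.
    """
    values = np.asarray(values, dtype=float)
    labels = np.atleast_1d(np.asarray(labels, dtype=float))
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    if values.ndim == 1:
        return recenter_reconstruction(values[:, None], labels, basis)[:, 0]
    if values.shape[1] != labels.size:
        raise ValueError("one label per trial required")
    nearest = basis.nearest_channel(labels)
    shifts = basis.zero_position - nearest
    k = basis.n_channels
    idx = (np.arange(k)[:, None] - shifts[None, :]) % k   # inverse of roll
    return values[idx, np.arange(values.shape[1])[None, :]]


def preprocess(dataset: BoldDataset, detrend_order: int = 0, zscore: bool = True) -> BoldDataset:
    """Per-run voxel time-series preparation: polynomial detrend (orders
    1–3, on the trial-major within-run time ordering) then z-scoring.

    Returns a new dataset; the generating truth block is carried over.
    White-noise synthetic data need neither step, but z-scoring is the
    analysis default because the real-data pipeline z-scores each run.
    """
    if detrend_order not in (0, 1, 2, 3):
        raise ValueError("detrend_order must be 0..3")
    data = dataset.data.astype(float).copy()
    n_runs, v, n_trs, tpr = data.shape
    for r in range(n_runs):
        ts = np.moveaxis(data[r], 1, 2).reshape(v, n_trs * tpr)  # voxel × time
        if detrend_order:
            x = np.vander(np.linspace(-1, 1, ts.shape[1]), detrend_order + 1)
            beta, *_ = np.linalg.lstsq(x, ts.T, rcond=None)
            ts = ts - (x @ beta).T
        if zscore:
            mu = ts.mean(axis=1, keepdims=True)
            sd = ts.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            ts = (ts - mu) / sd
        data[r] = np.moveaxis(ts.reshape(v, tpr, n_trs), 1, 2)
    return BoldDataset(data=data, design=dataset.design, truth=dict(dataset.truth))


def crossval_reconstruct_timecourse(
    dataset: BoldDataset,
    feature_dim: str,
    test_item: str = "pmi",
    train_item: str = "pmi",
    trs=None,
    train_labels_override=None,
) -> TimecourseReconstruction:
    """Leave-one-run-out reconstruction time course.

    For each requested (1-based) TR and each held-out run: train the
    encoding model on the remaining runs at that TR using the training
    item's labels, invert it on the held-out run at the same TR, and
    recenter each test trial's channel vector to the tested item's label.
    ``train_labels_override`` substitutes the training label vector (e.g. a
    permutation for null calibration) while leaving testing untouched.
    """
    if dataset.n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out")
    basis = (
        ChannelBasis.location() if feature_dim == "location" else ChannelBasis.orientation()
    )
    trs = tuple(range(1, N_TRS_PER_TRIAL + 1)) if trs is None else tuple(sorted(trs))
    train_labels = (
        np.asarray(train_labels_override, dtype=float)
        if train_labels_override is not None
        else dataset.design.labels(train_item, feature_dim)
    )
    test_labels = dataset.design.labels(test_item, feature_dim)
    n_runs, tpr = dataset.n_runs, dataset.trials_per_run
    run_of_trial = np.repeat(np.arange(n_runs), tpr)

    per_trial = {}
    for tr in trs:
        slab = dataset.tr_slab(tr)                      # runs × voxels × trials/run
        out = np.empty((basis.n_channels, dataset.design.n_trials))
        for held in range(n_runs):
            train_mask = run_of_trial != held
            b1 = np.concatenate(
                [slab[r] for r in range(n_runs) if r != held], axis=1
            )
            c1 = ideal_channel_matrix(basis, train_labels[train_mask])
            try:
                w = estimate_weights(b1, c1)
                c2 = invert_model(w, slab[held])
            except RankDeficiencyError as err:
                raise RankDeficiencyError(
                    f"fold with run {held} held out, TR {tr}: {err}"
                ) from err
            test_idx = np.where(~train_mask)[0]
            out[:, test_idx] = recenter_reconstruction(
                c2, test_labels[test_idx], basis
            )
        per_trial[tr] = out
    return TimecourseReconstruction(
        trs=trs, per_trial=per_trial, basis=basis,
        feature_dim=feature_dim, item=test_item,
    )
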