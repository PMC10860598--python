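"""Univariate load analyses: percent signal change, GLM voxel selection,
content/context load binning, per-TR load tests, delay-period sensitivity.

Load is defined by the inter-item distance in a feature dimension:
load-of-1 when the two samples share the feature (distance 0), load-of-2
otherwise.  Content load follows location distance, context load follows
orientation distance.  Percent signal change (PSC) is baseline-corrected
to the first TR of each trial and scaled by the run-mean signal
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import (
    EPOCH_DURATIONS,
    TR_SECONDS,
    TrialDesign,
)
from .stats import fdr_bh, paired_permutation_test
from .synth import BoldDataset, N_TRS_PER_TRIAL

__all__ = [
    "LoadAssignment",
    "assign_loads",
    "percent_signal_change",
    "dataset_psc",
    "double_gamma_hrf",
    "epoch_regressors",
    "glm_voxel_selection",
    "load_timecourse_test",
    "delay_load_sensitivity",
]

_PSC_EPS = 1e-6
DELAY_1_2_TRS = (8, 9, 10)   # 1-based TRs spanning the late first delay


@dataclass
class LoadAssignment:
    """Per-trial load levels derived deterministically from the design."""

    content_load: np.ndarray            # 1 | 2, from location distance
    context_load: np.ndarray            # 1 | 2, from orientation distance
    content_distance_level: np.ndarray  # |loc_dist| in {0,40,80,120,160}
    context_distance_level: np.ndarray  # |ori_dist| in {0,30,60,90}

    def load(self, role: str) -> np.ndarray:
        if role == "content":
            return self.content_load
        if role == "context":
            return self.context_load
        raise ValueError(f"unknown role {role!r}")


def assign_loads(design: TrialDesign) -> LoadAssignment:
    t = design.trials
    loc_d = np.abs(t["loc_dist"].to_numpy())
    ori_d = np.abs(t["ori_dist"].to_numpy())
    return LoadAssignment(
        content_load=np.where(loc_d == 0, 1, 2),
        context_load=np.where(ori_d == 0, 1, 2),
        content_distance_level=loc_d,
        context_distance_level=ori_d,
    )


def percent_signal_change(
    trial_timecourses: np.ndarray, run_mean, run_of_trial=None
) -> np.ndarray:
    """PSC per trial and TR: 100 * (x_t − x_1) / |run-mean intensity|.

    ``trial_timecourses`` is n_trials × n_TRs of ROI-mean signal;
    ``run_mean`` is a scalar or per-run vector (with ``run_of_trial``
    mapping trials to runs).  The first TR of every trial is the baseline,
    so PSC at TR 1 is identically 0.
    """
    x = np.atleast_2d(np.asarray(trial_timecourses, dtype=float))
    if x.shape[1] < 1:
        raise ValueError("need at least one TR")
    rm = np.asarray(run_mean, dtype=float)
    if rm.ndim == 0:
        denom = np.full(x.shape[0], float(rm))
    else:
        if run_of_trial is None:
            raise ValueError("run_of_trial required with per-run means")
        denom = rm[np.asarray(run_of_trial)]
    bad = np.abs(denom) < _PSC_EPS
    if np.any(bad):
        runs = (
            sorted(set(np.asarray(run_of_trial)[bad].tolist()))
            if run_of_trial is not None
            else "all"
        )
        raise ValueError(
            f"degenerate PSC denominator (|run mean| < {_PSC_EPS}) in run(s) {runs}; "
            "z-scored input has no intensity baseline"
        )
    return 100.0 * (x - x[:, :1]) / np.abs(denom)[:, None]


def dataset_psc(dataset: BoldDataset) -> np.ndarray:
    """ROI-mean PSC for every trial (n_trials × n_TRs, run-major order)."""
    tc = dataset.roi_mean()
    run_of_trial = np.repeat(np.arange(dataset.n_runs), dataset.trials_per_run)
    return percent_signal_change(tc, dataset.run_mean_intensity(), run_of_trial)


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 5 s, undershoot
    15 s, undershoot ratio 1/6), evaluated at times ``t`` in seconds."""
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, a=6, scale=1.0) - sps.gamma.pdf(t, a=16, scale=1.0) / 6.0
    return np.where(t >= 0, h, 0.0)


# (name, onset within trial in s, duration in s); impulses last one TR.
_EPOCHS = (
    ("sample", 0.0, TR_SECONDS),
    ("delay1_1", EPOCH_DURATIONS["sample"], EPOCH_DURATIONS["delay1_1"]),
    ("cue1", 10.0, TR_SECONDS),
    ("delay1_2", 12.0, EPOCH_DURATIONS["delay1_2"]),
    ("probe1", 20.0, TR_SECONDS),
    ("delay2", 22.5, TR_SECONDS),
    ("probe2", 27.5, TR_SECONDS),
)
EPOCH_NAMES = tuple(name for name, *_ in _EPOCHS)


def epoch_regressors(design: TrialDesign, run: int, grid_s: float = 0.5):
    """HRF-convolved task regressors for one run, sampled at acquired TRs.

    Builds each of the seven epoch regressors (impulses and boxcars) on a
    fine time grid over the run, convolves with the canonical HRF, and
    samples at the times of the stored trial-locked volumes.  Returns
    (X, sample_times): X is n_samples × 7 in EPOCH_NAMES order.
    """
    t = design.trials[design.trials["run"] == run]
    duration = design.run_duration_s(run)
    grid = np.arange(0.0, duration + grid_s, grid_s)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, grid_s))
    box = np.zeros((len(_EPOCHS), grid.size))
    for onset in t["onset_s"]:
        for i, (_, rel, dur) in enumerate(_EPOCHS):
            lo, hi = onset + rel, onset + rel + dur
            box[i, (grid >= lo) & (grid < hi)] = 1.0
    conv = np.stack([np.convolve(b, hrf, mode="full")[: grid.size] for b in box])
    conv *= grid_s  # approximate continuous convolution
    sample_times = (
        t["onset_s"].to_numpy()[:, None] + np.arange(N_TRS_PER_TRIAL)[None, :] * TR_SECONDS
    ).ravel()
    idx = np.rint(sample_times / grid_s).astype(int)
    return conv[:, idx].T, sample_times


def glm_voxel_selection(
    dataset: BoldDataset, target_regressor: str, k: int = 500
) -> np.ndarray:
    """Top-k voxels by the target epoch's GLM coefficient.

    Fits, per run, ordinary least squares of every voxel's trial-locked
    time series on the seven HRF-convolved epoch regressors plus intercept
    and linear drift; run-wise coefficients are averaged and voxels ranked
    by the target's mean coefficient.
    """
    if target_regressor not in EPOCH_NAMES:
        raise ValueError(f"target must be one of {EPOCH_NAMES}")
    if k > dataset.n_voxels:
        raise ValueError(f"k={k} exceeds {dataset.n_voxels} voxels")
    tgt = EPOCH_NAMES.index(target_regressor)
    betas = []
    for r in range(dataset.n_runs):
        x_task, times = epoch_regressors(dataset.design, r)
        drift = np.column_stack(
            [np.ones_like(times), (times - times.mean()) / np.ptp(times)]
        )
        x = np.column_stack([x_task, drift])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient GLM design matrix in run {r}"
            )
        # voxel × time, matching the sample_times ordering (trial-major)
        y = np.moveaxis(dataset.data[r], 1, 2).reshape(dataset.n_voxels, -1).T
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        betas.append(beta[tgt])
    score = np.mean(betas, axis=0)
    return np.argsort(score)[::-1][:k]


def _load_group_means(psc: np.ndarray, loads: LoadAssignment, role: str):
    lv = loads.load(role)
    if not (np.any(lv == 1) and np.any(lv == 2)):
        raise ValueError(f"both {role}-load groups must be nonempty")
    return psc[lv == 1].mean(axis=0), psc[lv == 2].mean(axis=0)


def load_timecourse_test(
    psc_per_subject,
    loads: LoadAssignment,
    role: str,
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-TR load-of-1 vs load-of-2 contrast across subjects.

    ``psc_per_subject`` is a sequence of (n_trials × n_TRs) PSC arrays;
    ``loads`` is one LoadAssignment shared by all subjects or a sequence of
    per-subject assignments (subjects normally have independently
    randomized schedules).  Per subject and TR the two load groups are
    averaged; a paired sign-flip permutation test compares them across
    subjects at each TR, with a BH-FDR mask across TRs.  Returns a frame
    with columns tr, mean_load1, mean_load2, p, significant.
    """
    psc_per_subject = list(psc_per_subject)
    if isinstance(loads, LoadAssignment):
        loads = [loads] * len(psc_per_subject)
    means1, means2 = [], []
    for psc, lo in zip(psc_per_subject, loads):
        m1, m2 = _load_group_means(np.asarray(psc, dtype=float), lo, role)
        means1.append(m1)
        means2.append(m2)
    m1 = np.stack(means1)        # subjects × TRs
    m2 = np.stack(means2)
    rng = np.random.default_rng(seed)
    ps = np.array(
        [
            paired_permutation_test(
                m2[:, tr], m1[:, tr], n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            for tr in range(m1.shape[1])
        ]
    )
    return pd.DataFrame(
        {
            "tr": np.arange(1, m1.shape[1] + 1),
            "mean_load1": m1.mean(axis=0),
            "mean_load2": m2.mean(axis=0),
            "p": ps,
            "significant": fdr_bh(ps, q=q),
        }
    )


def delay_load_sensitivity(
    psc: np.ndarray, loads: LoadAssignment, role: str, trs=DELAY_1_2_TRS
) -> float:
    """Late-delay load sensitivity for one subject: mean over TRs 8–10 of
    (load-of-2 PSC − load-of-1 PSC)."""
    psc = np.asarray(psc, dtype=float)
    trs = np.asarray(trs, dtype=int)
    if np.any(trs > psc.shape[1]) or np.any(trs < 1):
        raise ValueError(f"TRs {trs.tolist()} outside the available 1..{psc.shape[1]}")
    m1, m2 = _load_group_means(psc, loads, role)
    idx = trs - 1
    return float((m2[idx] - m1[idx]).mean())
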