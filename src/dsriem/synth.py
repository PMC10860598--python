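"""Synthetic voxel data with known tuning, priority regimes, and load effects.

Each voxel is assigned a preferred location and a preferred orientation;
its weight row over a channel basis is the basis activation of that
preference (plus small weight noise).  The per-TR voxel signal is the
linear encoding

    s(tr) = a_PMI(tr) * W @ c(PMI) + a_UMI(tr) * W @ c(UMI)   (per dimension)
          + baseline + load terms + white Gaussian noise,

where c(.) are idealized channel-response vectors and the amplitude
profiles a(.) play the role of HRF-convolved epoch gains.  "Remapping" of
the unprioritized item at selected TRs replaces c(UMI) by its reflection
about the channel mean, which flips the sign of the reconstruction slope
downstream while preserving the mean response.

Univariate load effects are additive, uniform over voxels: when the two
samples differ in a dimension (load-of-2), that dimension's per-TR load
profile is added.  A cohort generator couples per-subject neural load
gains to a behavioral response-time load effect with correlation
``behavior_coupling``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import ChannelBasis, ideal_channel_matrix
from .design import TrialDesign, build_design

__all__ = [
    "N_TRS_PER_TRIAL",
    "SynthConfig",
    "BoldDataset",
    "remap_channel_vector",
    "default_amp_profile",
    "simulate_subject",
    "simulate_cohort_with_behavior",
]

N_TRS_PER_TRIAL = 12  # 2-s TRs, trial onset through end of Probe 1

FEATURE_DIMS = ("location", "orientation")
# Role of each feature dimension in this task variant.
ROLE_OF_DIM = {"location": "content", "orientation": "context"}
DIM_OF_ROLE = {v: k for k, v in ROLE_OF_DIM.items()}


def default_amp_profile(item: str) -> np.ndarray:
    """Illustrative per-TR amplitude gains (12 TRs).

    Both items rise with the sample-evoked response and sustain through the
    delays; after Cue 1 (onset 10 s, TR 6; plus hemodynamic lag) the
    unprioritized item is attenuated.
    """
    prof = np.array([0.0, 0.3, 0.8, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    if item == "umi":
        prof = prof.copy()
        prof[7:] = 0.4
    elif item != "pmi":
        raise ValueError(f"unknown item {item!r}")
    return prof


def _zero_profile() -> np.ndarray:
    return np.zeros(N_TRS_PER_TRIAL)


@dataclass
class SynthConfig:
    """Generative settings for one synthetic subject / ROI regime.

    Amplitude profiles and remap TR sets are keyed by feature dimension
    ('location', 'orientation'); load-effect profiles by role ('content' =
    location distance, 'context' = orientation distance) and are added when
    the trial is load-of-2 on that role.  TR indices are 1-based.
    """

    n_voxels: int = 500
    noise_sd: float = 2.0
    baseline: float = 100.0
    weight_noise_sd: float = 0.05
    amp_pmi: dict = field(
        default_factory=lambda: {d: default_amp_profile("pmi") for d in FEATURE_DIMS}
    )
    amp_umi: dict = field(
        default_factory=lambda: {d: default_amp_profile("umi") for d in FEATURE_DIMS}
    )
    remap_trs: dict = field(default_factory=lambda: {d: frozenset() for d in FEATURE_DIMS})
    load_effect: dict = field(
        default_factory=lambda: {"content": _zero_profile(), "context": _zero_profile()}
    )
    load_gain_sd: float = 0.3
    behavior_coupling: float = 0.44
    rt_base_ms: float = 1000.0
    rt_effect_mean_ms: float = 100.0
    rt_effect_sd_ms: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in FEATURE_DIMS:
            for amp in (self.amp_pmi, self.amp_umi):
                amp[d] = np.asarray(amp[d], dtype=float)
                if amp[d].shape != (N_TRS_PER_TRIAL,):
                    raise ValueError(f"amplitude profile for {d} must have "
                                     f"{N_TRS_PER_TRIAL} entries")
            bad = [tr for tr in self.remap_trs.get(d, ()) if not 1 <= tr <= N_TRS_PER_TRIAL]
            if bad:
                raise ValueError(f"remap TR indices out of 1..{N_TRS_PER_TRIAL}: {bad}")
        for role in ("content", "context"):
            self.load_effect[role] = np.asarray(self.load_effect[role], dtype=float)
            if self.load_effect[role].shape != (N_TRS_PER_TRIAL,):
                raise ValueError("load_effect profiles must have one entry per TR")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class BoldDataset:
    """Per-subject numeric block: runs × voxels × TRs-per-trial × trials-per-run.

    Trials along the last axis follow the design's run-major row order.
    ``truth`` (synthetic data only) carries the generating weight matrices
    and regime flags for round-trip tests.
    """

    data: np.ndarray
    design: TrialDesign
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        r, v, t, j = self.data.shape
        if t != N_TRS_PER_TRIAL:
            raise ValueError(f"expected {N_TRS_PER_TRIAL} TRs per trial, got {t}")
        if r != self.design.n_runs or r * j != self.design.n_trials:
            raise ValueError("data dimensions inconsistent with design")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in data block")

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def trials_per_run(self) -> int:
        return self.data.shape[3]

    def tr_slab(self, tr: int) -> np.ndarray:
        """Voxel patterns at 1-based TR ``tr``: (runs, voxels, trials-per-run)."""
        return self.data[:, :, tr - 1, :]

    def roi_mean(self) -> np.ndarray:
        """Voxel-averaged per-trial time courses, (n_trials, n_TRs),
        run-major trial order."""
        m = self.data.mean(axis=1)                      # runs × TRs × trials
        return np.moveaxis(m, 1, 2).reshape(-1, self.data.shape[2])

    def run_mean_intensity(self) -> np.ndarray:
        """Mean signal intensity per run (over voxels, TRs, trials)."""
        return self.data.mean(axis=(1, 2, 3))


def remap_channel_vector(c: np.ndarray) -> np.ndarray:
    """Reflect channel vector(s) about the channel mean: 2*mean − c.

    An involution that preserves the mean; a center-peaked tuning profile
    becomes center-inverted, flipping the reconstruction slope's sign.
    Works on a k-vector or a k × n matrix (per-column mean preserved).
    """
    c = np.asarray(c, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least two channels")
    return 2.0 * c.mean(axis=0, keepdims=True) - c


def _voxel_weights(basis: ChannelBasis, n_voxels: int, weight_noise_sd: float, rng):
    prefs = rng.uniform(0.0, basis.period, size=n_voxels)
    w = ideal_channel_matrix(basis, prefs).T            # voxels × channels
    if weight_noise_sd > 0:
        w = w + rng.normal(0.0, weight_noise_sd, size=w.shape)
    return w


def simulate_subject(
    design: TrialDesign,
    cfg: SynthConfig,
    seed: int | None = None,
    load_gains: dict | None = None,
) -> BoldDataset:
    """Generate one subject's dataset under the linear encoding model.

    ``load_gains`` optionally scales the config's load-effect profiles per
    role (used by the cohort generator to inject between-subject
    variability).  Reproducible given ``seed`` (defaults to ``cfg.seed``).
    """
    bases = {"location": ChannelBasis.location(), "orientation": ChannelBasis.orientation()}
    for b in bases.values():
        if cfg.n_voxels < b.n_channels:
            raise ValueError(
                f"n_voxels={cfg.n_voxels} < {b.n_channels} channels; "
                "inversion would be underdetermined"
            )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gains = {"content": 1.0, "context": 1.0}
    if load_gains:
        gains.update(load_gains)

    n = design.n_trials
    n_runs, tpr = design.n_runs, design.trials_per_run
    v = cfg.n_voxels

    weights, wc = {}, {}
    for dim, basis in bases.items():
        w = _voxel_weights(basis, v, cfg.weight_noise_sd, rng)
        weights[dim] = w
        c_pmi = ideal_channel_matrix(basis, design.labels("pmi", dim))
        c_umi = ideal_channel_matrix(basis, design.labels("umi", dim))
        wc[dim] = {
            "pmi": w @ c_pmi,
            "umi": w @ c_umi,
            "umi_remap": w @ remap_channel_vector(c_umi),
        }

    t = design.trials
    load2 = {
        "content": (t["loc_dist"] != 0).to_numpy(float),
        "context": (t["ori_dist"] != 0).to_numpy(float),
    }

    signal = np.full((v, N_TRS_PER_TRIAL, n), cfg.baseline)
    for dim in FEATURE_DIMS:
        for tr in range(N_TRS_PER_TRIAL):
            umi_key = "umi_remap" if (tr + 1) in cfg.remap_trs[dim] else "umi"
            signal[:, tr, :] += (
                cfg.amp_pmi[dim][tr] * wc[dim]["pmi"]
                + cfg.amp_umi[dim][tr] * wc[dim][umi_key]
            )
    for role in ("content", "context"):
        # uniform over voxels: (TRs, trials) outer product with the load mask
        signal += (gains[role] * cfg.load_effect[role])[None, :, None] * load2[role][None, None, :]

    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)

    # run-major trial order -> (runs, voxels, TRs, trials-per-run)
    data = np.moveaxis(signal.reshape(v, N_TRS_PER_TRIAL, n_runs, tpr), 2, 0)
    truth = {
        "W_location": weights["location"],
        "W_orientation": weights["orientation"],
        "config": cfg,
        "load_gains": gains,
        "remap_trs": {d: sorted(cfg.remap_trs[d]) for d in FEATURE_DIMS},
    }
    return BoldDataset(data=np.ascontiguousarray(data), design=design, truth=truth)


def simulate_cohort_with_behavior(
    n_subjects: int,
    cfg: SynthConfig,
    design: TrialDesign | None = None,
    seed: int | None = None,
):
    """Simulate a cohort plus a response-time table with coupled load effects.

    Per-subject neural load gains g_s ~ Normal(1, load_gain_sd) scale the
    config's load-effect profiles; the behavioral RT load effect is
    rho * standardize(g_s) + sqrt(1 - rho^2) * noise (rho =
    ``cfg.behavior_coupling``), mapped to milliseconds.  Returns
    (datasets, behavior) where behavior has one row per subject ×
    role × load level.

    With ``design=None`` every subject receives an independently
    randomized schedule, as in the scanner; passing a design shares it.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    designs = (
        [build_design(seed=int(s)) for s in root.integers(2**31, size=n_subjects)]
        if design is None
        else [design] * n_subjects
    )
    gains, behavior = draw_cohort_behavior(n_subjects, cfg, root)
    datasets = []
    for s in range(n_subjects):
        sub_seed = int(root.integers(2**31))
        ds = simulate_subject(
            designs[s], cfg, seed=sub_seed,
            load_gains={r: gains.loc[s, r] for r in ("content", "context")},
        )
        ds.truth["subject"] = s
        datasets.append(ds)
    return datasets, behavior


def draw_cohort_behavior(n_subjects: int, cfg: SynthConfig, rng):
    """Draw per-subject load gains and the coupled RT table.

    Returns (gains, behavior): gains indexed by subject with columns
    'content'/'context'; behavior long-format with columns subject, role,
    load, rt_ms.
    """
    rho = cfg.behavior_coupling
    if not -1.0 <= rho <= 1.0:
        raise ValueError("behavior_coupling must be in [-1, 1]")
    gains = pd.DataFrame(
        rng.normal(1.0, cfg.load_gain_sd, size=(n_subjects, 2)),
        columns=["content", "context"],
    )
    gains.index.name = "subject"
    rows = []
    for role in ("content", "context"):
        g = gains[role].to_numpy()
        z = (g - g.mean()) / g.std(ddof=0) if g.std(ddof=0) > 0 else np.zeros_like(g)
        eps = rng.standard_normal(n_subjects)
        effect = cfg.rt_effect_mean_ms + cfg.rt_effect_sd_ms * (
            rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        )
        for s in range(n_subjects):
            rows.append((s, role, 1, cfg.rt_base_ms))
            rows.append((s, role, 2, cfg.rt_base_ms + effect[s]))
    behavior = pd.DataFrame(rows, columns=["subject", "role", "load", "rt_ms"])
    return gains, behavior


def behavioral_load_effect(behavior: pd.DataFrame, role: str) -> np.ndarray:
    """Per-subject RT load effect (load-2 minus load-1 RT, ms) for a role."""
    b = behavior[behavior["role"] == role].pivot(
        index="subject", columns="load", values="rt_ms"
    )
    return (b[2] - b[1]).to_numpy()
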