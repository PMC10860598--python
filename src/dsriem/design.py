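"""Dual-serial-retrocue (DSR) trial schedules.

The DSR task presents two sample items, each defined by a polar-angle
location (content, 360° space) and a bar orientation (context, 180° space).
An orientation retrocue (Cue 1) prioritizes one item for the first probe;
a second retrocue either stays with it or switches to the other item.

The schedule fully crosses the signed inter-item distance in location
(9 levels), the signed distance in orientation (6 levels) and the second
cue's status (stay/switch), giving 108 unique trial types; ``reps`` copies
of each are shuffled into runs of 12 trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LOCATION_BASE",
    "ORIENTATION_BASE",
    "LOCATION_DISTANCES",
    "ORIENTATION_DISTANCES",
    "CUE2_STATUSES",
    "PROBE_OFFSETS",
    "ITI_VALUES",
    "EPOCH_DURATIONS",
    "TRIALS_PER_RUN",
    "N_DUMMY_TRS",
    "TR_SECONDS",
    "ScheduleError",
    "circular_difference",
    "enumerate_trial_types",
    "build_design",
    "design_summary",
    "TrialDesign",
]

# Stimulus sets: locations on an imaginary circle (polar angle), bar
# orientations on the 180°-periodic orientation circle.
LOCATION_BASE = tuple(range(20, 360, 40))          # 20, 60, ..., 340
ORIENTATION_BASE = tuple(range(15, 180, 30))       # 15, 45, ..., 165
LOCATION_DISTANCES = tuple(range(-160, 161, 40))   # signed, 9 levels
ORIENTATION_DISTANCES = (-60, -30, 0, 30, 60, 90)  # signed, 6 levels
CUE2_STATUSES = ("stay", "switch")
PROBE_OFFSETS = (15, 25, 35)                       # nonmatch probes only
ITI_VALUES = (6, 8, 10)                            # seconds, jittered

TRIALS_PER_RUN = 12
N_DUMMY_TRS = 4          # discarded volumes at the start of each run
TR_SECONDS = 2.0

# Per-epoch durations in seconds.  Probe 2 matches Probe 1 (2.5 s) so a run
# of 12 trials with balanced ITIs lasts exactly 464 s including dummies.
EPOCH_DURATIONS = {
    "sample": 2.0,
    "delay1_1": 8.0,
    "cue1": 2.0,
    "delay1_2": 8.0,
    "probe1": 2.5,
    "delay2_1": 1.0,
    "cue2": 2.0,
    "delay2_2": 2.0,
    "probe2": 2.5,
}
TRIAL_SECONDS = sum(EPOCH_DURATIONS.values())  # 30 s sample-to-probe2-offset

_COLUMNS = [
    "run", "trial", "loc1", "ori1", "loc2", "ori2", "jitter",
    "loc_dist", "ori_dist", "cued_item", "cue2_status",
    "probe_match", "probe_offset", "iti", "onset_s",
]


class ScheduleError(ValueError):
    """Raised when a schedule cannot satisfy its counterbalancing contract."""


def circular_difference(a, b, period):
    """Signed circular difference a − b wrapped to (−period/2, period/2].

    This is the convention under which the printed distance sets
    {−160,…,160} (period 360) and {−60,…,90} (period 180) are closed.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.mod(d, period)
    return np.where(d > period / 2, d - period, d)


def enumerate_trial_types(
    loc_distances=LOCATION_DISTANCES,
    ori_distances=ORIENTATION_DISTANCES,
    cue2_statuses=CUE2_STATUSES,
):
    """Full crossing of (loc_distance, ori_distance, cue2_status).

    With the default factor sets this yields the 108 unique trial types.
    """
    return list(itertools.product(loc_distances, ori_distances, cue2_statuses))


@dataclass
class TrialDesign:
    """A complete per-subject schedule: one row per trial.

    ``trials`` columns: run, trial (index within run), loc1/ori1/loc2/ori2
    (degrees, jitter already applied to locations), jitter, signed loc_dist
    and ori_dist, cued_item (1|2), cue2_status, probe_match, probe_offset
    (NaN on match trials), iti (s), onset_s (s from run start, after dummy
    volumes).
    """

    trials: pd.DataFrame
    timing: dict = field(default_factory=lambda: dict(EPOCH_DURATIONS))
    n_dummy_trs: int = N_DUMMY_TRS
    trials_per_run: int = TRIALS_PER_RUN
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_runs(self) -> int:
        return int(self.trials["run"].max()) + 1

    def labels(self, item: str, feature_dim: str) -> np.ndarray:
        """Feature labels per trial for ``item`` in {'pmi','umi'} and
        ``feature_dim`` in {'location','orientation'} (Cue-1 priority)."""
        t = self.trials
        if feature_dim == "location":
            a, b = t["loc1"].to_numpy(), t["loc2"].to_numpy()
        elif feature_dim == "orientation":
            a, b = t["ori1"].to_numpy(), t["ori2"].to_numpy()
        else:
            raise ValueError(f"unknown feature_dim {feature_dim!r}")
        cued_first = t["cued_item"].to_numpy() == 1
        if item == "pmi":
            return np.where(cued_first, a, b)
        if item == "umi":
            return np.where(cued_first, b, a)
        raise ValueError(f"unknown item {item!r}")

    def run_duration_s(self, run: int | None = None) -> float:
        """Duration of one run (or each run) including dummy volumes."""
        t = self.trials if run is None else self.trials[self.trials["run"] == run]
        if run is None:
            per_run = t.groupby("run")["iti"].sum() + self.trials_per_run * TRIAL_SECONDS
            return (per_run + self.n_dummy_trs * TR_SECONDS).to_numpy()
        return float(
            t["iti"].sum() + len(t) * TRIAL_SECONDS + self.n_dummy_trs * TR_SECONDS
        )

    def to_tsv(self, path) -> None:
        out = self.trials.copy()
        for c in ("loc1", "ori1", "loc2", "ori2", "jitter", "onset_s"):
            out[c] = out[c].map(lambda v: f"{v:.3f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialDesign":
        t = pd.read_csv(path, sep="\t")
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ScheduleError(f"events table missing columns: {missing}")
        return cls(trials=t[_COLUMNS])


def _balanced_cued_items(n_cells: int, reps: int, rng) -> np.ndarray:
    """Per-cell cued_item assignments, as even as possible within each cell
    and exactly 50/50 over the session (odd cells' extra item alternates)."""
    base = np.tile([1, 2], reps // 2 + 1)[: reps - reps % 2]
    out = np.empty((n_cells, reps), dtype=int)
    extras = np.repeat([1, 2], [n_cells // 2, n_cells - n_cells // 2])
    rng.shuffle(extras)
    for i in range(n_cells):
        row = list(base)
        if reps % 2:
            row.append(int(extras[i]))
        rng.shuffle(row)
        out[i] = row
    return out


def _balanced_choice(values, n: int, rng) -> np.ndarray:
    """n draws from ``values`` with counts as equal as possible, shuffled."""
    values = np.asarray(values)
    reps = np.tile(values, n // len(values) + 1)[:n]
    rng.shuffle(reps)
    return reps


def build_design(
    seed: int,
    reps: int = 3,
    jitter_max: float = 10.0,
    trial_types=None,
) -> TrialDesign:
    """Build a fully counterbalanced DSR schedule.

    Each of the 108 (loc_distance × ori_distance × cue2_status) cells appears
    exactly ``reps`` times; trials are shuffled into runs of 12. Sample 1
    features are drawn uniformly from the base sets; sample 2 adds the cell's
    signed distance. A shared location jitter in [0, jitter_max] keeps the
    pair's distance intact while covering the full circle. Probe match is
    balanced 50/50 (nonmatch offsets balanced over 15/25/35°); ITIs are
    balanced within each run (4 each of 6/8/10 s) so all runs last 464 s.
    """
    if reps < 1:
        raise ScheduleError("reps must be >= 1")
    types = enumerate_trial_types() if trial_types is None else list(trial_types)
    n_trials = len(types) * reps
    if n_trials % TRIALS_PER_RUN:
        raise ScheduleError(
            f"{len(types)} types x {reps} reps = {n_trials} trials; "
            f"{n_trials % TRIALS_PER_RUN} left over after filling runs of "
            f"{TRIALS_PER_RUN}"
        )
    rng = np.random.default_rng(seed)

    cued = _balanced_cued_items(len(types), reps, rng)
    rows = []
    for i, (loc_d, ori_d, cue2) in enumerate(types):
        for r in range(reps):
            rows.append((loc_d, ori_d, cue2, cued[i, r]))
    df = pd.DataFrame(rows, columns=["loc_dist", "ori_dist", "cue2_status", "cued_item"])

    n = len(df)
    base_loc = rng.choice(LOCATION_BASE, size=n)
    base_ori = rng.choice(ORIENTATION_BASE, size=n)
    jitter = rng.uniform(0.0, jitter_max, size=n)
    df["jitter"] = jitter
    df["loc1"] = np.mod(base_loc + jitter, 360.0)
    df["ori1"] = base_ori.astype(float)
    df["loc2"] = np.mod(df["loc1"] + df["loc_dist"], 360.0)
    df["ori2"] = np.mod(df["ori1"] + df["ori_dist"], 180.0)

    match = np.zeros(n, dtype=bool)
    match[rng.permutation(n)[: n // 2]] = True
    df["probe_match"] = match
    offsets = np.full(n, np.nan)
    offsets[~match] = _balanced_choice(PROBE_OFFSETS, int((~match).sum()), rng)
    df["probe_offset"] = offsets

    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    df["run"] = np.arange(n) // TRIALS_PER_RUN
    df["trial"] = np.arange(n) % TRIALS_PER_RUN

    iti = np.concatenate(
        [_balanced_choice(ITI_VALUES, TRIALS_PER_RUN, rng) for _ in range(n // TRIALS_PER_RUN)]
    ).astype(float)
    df["iti"] = iti

    onset = np.empty(n)
    start = N_DUMMY_TRS * TR_SECONDS
    for r in range(n // TRIALS_PER_RUN):
        sl = slice(r * TRIALS_PER_RUN, (r + 1) * TRIALS_PER_RUN)
        gaps = TRIAL_SECONDS + iti[sl]
        onset[sl] = start + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    df["onset_s"] = onset

    return TrialDesign(trials=df[_COLUMNS], seed=seed)


def design_summary(design: TrialDesign) -> dict:
    """Counterbalancing report: factor proportions, per-cell counts, run
    durations."""
    t = design.trials
    if len(t) == 0:
        raise ScheduleError("empty design")
    cells = t.groupby(["loc_dist", "ori_dist", "cue2_status"]).size()
    return {
        "n_trials": len(t),
        "n_runs": design.n_runs,
        "trials_per_run": t.groupby("run").size().to_dict(),
        "prop_ori_dist_zero": float((t["ori_dist"] == 0).mean()),
        "prop_loc_dist_zero": float((t["loc_dist"] == 0).mean()),
        "prop_switch": float((t["cue2_status"] == "switch").mean()),
        "prop_probe_match": float(t["probe_match"].mean()),
        "cell_counts": cells,
        "run_duration_s": design.run_duration_s(),
    }
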