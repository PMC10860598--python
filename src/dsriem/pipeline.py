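"""End-to-end orchestration: simulate → preprocess → reconstruct → test →
adjudicate → report.

ROIs are synthetic labels ("EVC", "IPS") with independent generative
regimes, so each competing model's predicted sign pattern can be
instantiated and recovered.  A regime is expressed as the predicted sign
('+', '0', '-') of each role × item cell during the late first delay; the
default configuration instantiates the study's concluded pattern
(functional-model regime in early visual cortex, hybrid regime in IPS)
together with the observed univariate load profiles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import ChannelBasis
from .design import TrialDesign, build_design, design_summary
from .iem import crossval_reconstruct_timecourse, preprocess
from .load import (
    DELAY_1_2_TRS,
    LoadAssignment,
    assign_loads,
    dataset_psc,
    delay_load_sensitivity,
    load_timecourse_test,
)
from .stats import (
    MODEL_PREDICTIONS,
    ModelAdjudication,
    adjudicate_models,
    bootstrap_difference_test,
    bootstrap_slope_test,
    fdr_bh,
    pearson_correlation,
)
from .synth import (
    DIM_OF_ROLE,
    N_TRS_PER_TRIAL,
    SynthConfig,
    behavioral_load_effect,
    draw_cohort_behavior,
    simulate_subject,
)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "CohortArrays",
    "apply_cell_pattern",
    "roi_config_from_pattern",
    "default_roi_patterns",
    "default_load_profiles",
    "model_regime_rois",
    "simulate_and_reduce",
    "analyze_cohort",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("dsriem")

ROIS = ("EVC", "IPS")
ITEMS = ("pmi", "umi")
ROLES = ("content", "context")
CELL_KEYS = tuple((role, item) for role in ROLES for item in ITEMS)
_DELAY_TRS = tuple(range(8, N_TRS_PER_TRIAL + 1))


def apply_cell_pattern(cfg: SynthConfig, role: str, item: str, sign: str,
                       trs=_DELAY_TRS) -> SynthConfig:
    """Return a config whose late-delay regime realizes ``sign`` for a cell.

    '+' keeps the item's amplitude positive over ``trs``; '0' silences it;
    '-' (unprioritized item only) keeps it positive but remaps its channel
    vector at those TRs, producing a center-inverted reconstruction.
    """
    dim = DIM_OF_ROLE[role]
    amp_pmi = {d: v.copy() for d, v in cfg.amp_pmi.items()}
    amp_umi = {d: v.copy() for d, v in cfg.amp_umi.items()}
    remap = {d: frozenset(s) for d, s in cfg.remap_trs.items()}
    idx = np.asarray(trs, dtype=int) - 1
    amp = amp_pmi if item == "pmi" else amp_umi
    if sign == "+":
        pass
    elif sign == "0":
        amp[dim][idx] = 0.0
    elif sign == "-":
        if item != "umi":
            raise ValueError("a remapped (negative) regime applies to the UMI only")
        remap[dim] = frozenset(remap[dim] | set(int(t) for t in trs))
    else:
        raise ValueError(f"pattern sign must be '+', '0' or '-', got {sign!r}")
    return cfg.with_(amp_pmi=amp_pmi, amp_umi=amp_umi, remap_trs=remap)


def roi_config_from_pattern(base: SynthConfig, pattern: dict,
                            trs=_DELAY_TRS) -> SynthConfig:
    """Apply a {(role, item) or 'role_item': sign} pattern to a base config."""
    cfg = base
    for key, sign in pattern.items():
        role, item = key if isinstance(key, tuple) else tuple(key.rsplit("_", 1))
        cfg = apply_cell_pattern(cfg, role, item, sign, trs=trs)
    return cfg


def default_roi_patterns() -> dict:
    """The study's concluded regime: functional-model predictions in early
    visual cortex, hybrid-model predictions in IPS."""
    pats = {}
    for roi, model in (("EVC", "functional"), ("IPS", "hybrid")):
        pats[roi] = {
            (role, item): MODEL_PREDICTIONS[model][(roi, role, item)]
            for role, item in CELL_KEYS
        }
    return pats


def default_load_profiles() -> dict:
    """Observed univariate load regimes per ROI (signal units, ~PSC %):
    early visual cortex responds to content load only during the
    sample-evoked response (TRs 2–4); IPS responds to content load
    throughout the trial and to context load across Cue 1 and the first
    delay (TRs 7–10)."""
    def prof(trs, amp=0.3):
        p = np.zeros(N_TRS_PER_TRIAL)
        p[np.asarray(trs) - 1] = amp
        return p

    return {
        "EVC": {"content": prof((2, 3, 4)), "context": np.zeros(N_TRS_PER_TRIAL)},
        "IPS": {"content": prof(range(2, 13)), "context": prof((7, 8, 9, 10))},
    }


def model_regime_rois(model: str, base: SynthConfig) -> dict:
    """Per-ROI patterns realizing one model's predicted sign table."""
    return {
        roi: {(role, item): MODEL_PREDICTIONS[model][(roi, role, item)]
              for role, item in CELL_KEYS}
        for roi in ROIS
    }


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full analysis run."""

    design_seed: int = 1
    reps: int = 3
    jitter_max: float = 10.0
    n_subjects: int = 24
    cohort_seed: int = 7
    analysis_seed: int = 11
    synth: SynthConfig = field(default_factory=SynthConfig)
    roi_patterns: dict = field(default_factory=default_roi_patterns)
    roi_load_profiles: dict = field(default_factory=default_load_profiles)
    roi_overrides: dict = field(default_factory=dict)
    tr_of_interest: int = 10
    trs: tuple = tuple(range(1, N_TRS_PER_TRIAL + 1))
    n_boot: int = 10_000
    n_perm: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    fdr_family: str = "per_trace"      # or "across_rois"
    zscore: bool = True
    detrend_order: int = 0
    outdir: str = "dsriem_out"

    def __post_init__(self):
        if not 1 <= self.tr_of_interest <= N_TRS_PER_TRIAL:
            raise ValueError("tr_of_interest must be in 1..12")
        for name, v in (("alpha", self.alpha), ("fdr_q", self.fdr_q)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.fdr_family not in ("per_trace", "across_rois"):
            raise ValueError("fdr_family must be 'per_trace' or 'across_rois'")
        self.trs = tuple(sorted(set(int(t) for t in self.trs) | {self.tr_of_interest}))

    def roi_config(self, roi: str) -> SynthConfig:
        cfg = self.synth
        if roi in self.roi_load_profiles:
            cfg = cfg.with_(load_effect={
                r: np.asarray(p, dtype=float)
                for r, p in self.roi_load_profiles[roi].items()
            })
        if roi in self.roi_overrides:
            cfg = cfg.with_(**self.roi_overrides[roi])
        if roi in self.roi_patterns:
            cfg = roi_config_from_pattern(cfg, self.roi_patterns[roi])
        return cfg

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, SynthConfig):
                return {k2: clean(v2) for k2, v2 in vars(v).items()}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (set, frozenset)):
                return sorted(v)
            if isinstance(v, dict):
                return {
                    ("_".join(k2) if isinstance(k2, tuple) else str(k2)): clean(v2)
                    for k2, v2 in v.items()
                }
            if isinstance(v, tuple):
                return list(v)
            return v

        return {k: clean(v) for k, v in vars(self).items()}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "roi_patterns" in kwargs:
            kwargs["roi_patterns"] = {
                roi: {tuple(k.rsplit("_", 1)): s for k, s in cells.items()}
                for roi, cells in kwargs["roi_patterns"].items()
            }
        if "roi_load_profiles" in kwargs:
            kwargs["roi_load_profiles"] = {
                roi: {r: np.asarray(p, dtype=float) for r, p in d.items()}
                for roi, d in kwargs["roi_load_profiles"].items()
            }
        if "trs" in kwargs:
            kwargs["trs"] = tuple(kwargs["trs"])
        return cls(**kwargs)


@dataclass
class CohortArrays:
    """Reduced per-subject quantities the group analysis needs.

    Each subject has an independently randomized schedule (as in the
    scanner), so ``designs`` and ``loads`` are per-subject lists.
    ``curves[roi][(role, item)]``: subjects × n_trs × k recentered mean
    reconstructions; ``psc[roi]``: subjects × n_trials × 12 percent signal
    change; ``behavior``: long-format RT table.
    """

    designs: list
    loads: list
    curves: dict
    psc: dict
    behavior: pd.DataFrame
    gains: pd.DataFrame


@dataclass
class AnalysisReport:
    """All tables a full run produces, plus provenance."""

    provenance: dict
    design_summary: dict
    mean_curves: pd.DataFrame         # roi, role, item, tr, offset, response
    timecourse_stats: pd.DataFrame    # roi, role, item, tr, slope, p, ...
    prereg_cells: pd.DataFrame        # the 8 TR-of-interest cells
    adjudication: ModelAdjudication
    load_tests: pd.DataFrame
    load_sensitivity: pd.DataFrame
    behavior: pd.DataFrame
    brain_behavior: pd.DataFrame


def reduce_subject(dataset, trs, zscore=True, detrend_order=0):
    """Reduce one subject's dataset to recentered mean curves and PSC.

    Returns (curves, psc): curves maps (role, item) to n_trs × k arrays.
    PSC is computed on the raw-intensity data; reconstruction on the
    z-scored (and optionally detrended) data.
    """
    psc = dataset_psc(dataset)
    prepped = (
        preprocess(dataset, detrend_order=detrend_order, zscore=zscore)
        if (zscore or detrend_order) else dataset
    )
    curves = {}
    for role, item in CELL_KEYS:
        rec = crossval_reconstruct_timecourse(
            prepped, DIM_OF_ROLE[role], test_item=item, trs=trs
        )
        curves[(role, item)] = rec.mean_curves
    return curves, psc


def simulate_and_reduce(cfg: PipelineConfig, keep_raw: bool = False):
    """Simulate the cohort for every ROI and reduce to group-analysis arrays.

    Raw voxel blocks are discarded subject-by-subject unless ``keep_raw``;
    with the default 500-voxel, 27-run geometry a kept cohort is large.
    Returns CohortArrays (and, if keep_raw, a dict of datasets).

    Every subject receives an independently randomized schedule (derived
    from ``design_seed``).  A schedule shared across subjects would turn
    its idiosyncratic label imbalance into a fixed cohort-level bias that
    the bootstrap then "detects" in truly silent conditions.
    """
    droot = np.random.default_rng(cfg.design_seed)
    designs = [
        build_design(int(s), reps=cfg.reps, jitter_max=cfg.jitter_max)
        for s in droot.integers(2**31, size=cfg.n_subjects)
    ]
    loads = [assign_loads(d) for d in designs]
    root = np.random.default_rng(cfg.cohort_seed)
    gains, behavior = draw_cohort_behavior(cfg.n_subjects, cfg.synth, root)
    subject_seeds = root.integers(2**31, size=(cfg.n_subjects, len(ROIS)))

    roi_cfgs = {roi: cfg.roi_config(roi) for roi in ROIS}
    curves = {roi: {cell: [] for cell in CELL_KEYS} for roi in ROIS}
    psc = {roi: [] for roi in ROIS}
    raw = {roi: [] for roi in ROIS} if keep_raw else None
    for s in range(cfg.n_subjects):
        g = {r: float(gains.loc[s, r]) for r in ROLES}
        for j, roi in enumerate(ROIS):
            ds = simulate_subject(
                designs[s], roi_cfgs[roi], seed=int(subject_seeds[s, j]), load_gains=g
            )
            sub_curves, sub_psc = reduce_subject(
                ds, cfg.trs, cfg.zscore, cfg.detrend_order
            )
            for cell, mc in sub_curves.items():
                curves[roi][cell].append(mc)
            psc[roi].append(sub_psc)
            if keep_raw:
                raw[roi].append(ds)
        log.info("subject %d/%d simulated and reconstructed", s + 1, cfg.n_subjects)
    arrays = CohortArrays(
        designs=designs,
        loads=loads,
        curves={roi: {c: np.stack(v) for c, v in d.items()}
                for roi, d in curves.items()},
        psc={roi: np.stack(v) for roi, v in psc.items()},
        behavior=behavior,
        gains=gains,
    )
    return (arrays, raw) if keep_raw else arrays


def _basis_for_role(role: str) -> ChannelBasis:
    return (ChannelBasis.location() if DIM_OF_ROLE[role] == "location"
            else ChannelBasis.orientation())


def analyze_cohort(cfg: PipelineConfig, arrays: CohortArrays) -> AnalysisReport:
    """Group inference on reduced cohort arrays; see module docs."""
    summary = design_summary(arrays.designs[0])
    arng = np.random.default_rng(cfg.analysis_seed)
    tr_pos = {tr: i for i, tr in enumerate(cfg.trs)}

    tc_rows, curve_rows = [], []
    cell_tests = {}
    for roi in ROIS:
        for role in ROLES:
            basis = _basis_for_role(role)
            stacked = {item: arrays.curves[roi][(role, item)] for item in ITEMS}
            for item in ITEMS:
                for tr in cfg.trs:
                    sub = stacked[item][:, tr_pos[tr], :]
                    test = bootstrap_slope_test(
                        sub, basis, n_boot=cfg.n_boot,
                        seed=int(arng.integers(2**31)),
                    )
                    if tr == cfg.tr_of_interest:
                        cell_tests[(roi, role, item)] = test
                    tc_rows.append((roi, role, item, tr, test.point_estimate,
                                    test.p_two_tailed, test.p_is_bound,
                                    test.n_boot, test.seed))
                    for off, resp in zip(basis.offsets, sub.mean(axis=0)):
                        curve_rows.append((roi, role, item, tr, off, resp))
            for tr in cfg.trs:
                test = bootstrap_difference_test(
                    stacked["pmi"][:, tr_pos[tr], :],
                    stacked["umi"][:, tr_pos[tr], :],
                    basis, n_boot=cfg.n_boot, seed=int(arng.integers(2**31)),
                )
                tc_rows.append((roi, role, "pmi-umi", tr, test.point_estimate,
                                test.p_two_tailed, test.p_is_bound,
                                test.n_boot, test.seed))
    timecourse = pd.DataFrame(
        tc_rows,
        columns=["roi", "role", "item", "tr", "slope", "p", "p_is_bound",
                 "n_boot", "seed"],
    )
    fam_cols = ["roi", "role", "item"] if cfg.fdr_family == "per_trace" else ["role", "item"]
    timecourse["significant"] = False
    for _, idx in timecourse.groupby(fam_cols).groups.items():
        timecourse.loc[idx, "significant"] = fdr_bh(
            timecourse.loc[idx, "p"].to_numpy(), q=cfg.fdr_q
        )
    mean_curves = pd.DataFrame(
        curve_rows,
        columns=["roi", "role", "item", "tr", "channel_offset_deg", "response"],
    )

    adjudication = adjudicate_models(cell_tests, alpha=cfg.alpha)
    prereg = pd.DataFrame(
        [(roi, role, item, cfg.tr_of_interest, t.point_estimate, t.p_two_tailed,
          t.p_is_bound, t.n_boot, t.seed, adjudication.observed[(roi, role, item)])
         for (roi, role, item), t in cell_tests.items()],
        columns=["roi", "role", "item", "tr", "slope", "p", "p_is_bound",
                 "n_boot", "seed", "classification"],
    )

    load_rows, sens_rows, bb_rows = [], [], []
    for roi in ROIS:
        for role in ROLES:
            tab = load_timecourse_test(
                arrays.psc[roi], arrays.loads, role, n_perm=cfg.n_perm,
                q=cfg.fdr_q, seed=int(arng.integers(2**31)),
            )
            tab.insert(0, "role", role)
            tab.insert(0, "roi", roi)
            load_rows.append(tab)
            sens = np.array([
                delay_load_sensitivity(p, lo, role, trs=DELAY_1_2_TRS)
                for p, lo in zip(arrays.psc[roi], arrays.loads)
            ])
            sens_rows.extend((roi, role, s, v) for s, v in enumerate(sens))
            rt_effect = behavioral_load_effect(arrays.behavior, role)
            r, r2, p = pearson_correlation(sens, rt_effect)
            bb_rows.append((roi, role, r, r2, p, len(sens)))

    summary_ser = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in summary.items() if k != "cell_counts"
    }
    summary_ser["cell_counts_min"] = int(summary["cell_counts"].min())
    summary_ser["cell_counts_max"] = int(summary["cell_counts"].max())

    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seeds": {"design": cfg.design_seed, "cohort": cfg.cohort_seed,
                  "analysis": cfg.analysis_seed},
    }
    return AnalysisReport(
        provenance=provenance,
        design_summary=summary_ser,
        mean_curves=mean_curves,
        timecourse_stats=timecourse,
        prereg_cells=prereg,
        adjudication=adjudication,
        load_tests=pd.concat(load_rows, ignore_index=True),
        load_sensitivity=pd.DataFrame(
            sens_rows, columns=["roi", "role", "subject", "value"]
        ),
        behavior=arrays.behavior,
        brain_behavior=pd.DataFrame(
            bb_rows, columns=["roi", "role", "r", "r_squared", "p", "n"]
        ),
    )


def run_full_analysis(cfg: PipelineConfig) -> AnalysisReport:
    """Simulate a cohort under the configured regimes and analyze it."""
    return analyze_cohort(cfg, simulate_and_reduce(cfg))


_TABLES = (
    ("mean_curves", "reconstruction_curves.tsv"),
    ("timecourse_stats", "slope_tests.tsv"),
    ("prereg_cells", "prereg_cells.tsv"),
    ("load_tests", "load_tests.tsv"),
    ("load_sensitivity", "load_sensitivity.tsv"),
    ("behavior", "behavior.tsv"),
    ("brain_behavior", "brain_behavior.tsv"),
)


def write_report(report: AnalysisReport, outdir) -> list:
    """Write all report tables (TSV) and the JSON summary; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, name in _TABLES:
        path = out / name
        getattr(report, attr).to_csv(path, sep="\t", index=False)
        written.append(path)
    summary = {
        "provenance": report.provenance,
        "design_summary": report.design_summary,
        "adjudication": report.adjudication.to_dict(),
    }
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(path)
    log.info("report written to %s (%d files)", out, len(written))
    return written
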