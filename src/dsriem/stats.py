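"""Inference on recentered channel-response reconstructions.

The strength of a reconstruction is summarized by a collapse-and-slope
statistic: channels are paired by absolute offset from the 0° center,
paired values averaged, and the collapsed curve regressed on offset rank
ordered from the farthest offset to the center, so a center-peaked curve
yields a positive slope and a center-inverted ("remapped") curve a
negative one.

Group inference resamples subjects with replacement, averages their
curves, and recomputes the slope; the two-tailed p is twice the smaller
of the fractions of positive and negative resampled slopes.  A paired
sign-flip permutation test, Benjamini–Hochberg FDR, an exact
noncentral-t power routine, Pearson correlation, and adjudication of the
observed sign pattern against the three competing models round out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .basis import ChannelBasis

__all__ = [
    "SlopeTest",
    "ModelAdjudication",
    "MODEL_PREDICTIONS",
    "collapse_curve",
    "reconstruction_slope",
    "slope_operator",
    "bootstrap_slope_test",
    "bootstrap_difference_test",
    "fdr_bh",
    "required_sample_size",
    "paired_permutation_test",
    "pearson_correlation",
    "adjudicate_models",
]


def collapse_curve(curve: np.ndarray, basis: ChannelBasis):
    """Average channels paired by absolute offset; order farthest → center.

    Returns (ranks, values): ranks 0,1,… with the 0°-offset channel at the
    highest rank.  An unpaired half-period channel (the +90° orientation
    offset) enters as its own point.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (basis.n_channels,):
        raise ValueError("curve length must match the basis channel count")
    offs = basis.offsets
    abs_levels = np.unique(np.abs(offs))[::-1]          # farthest first
    values = np.array([curve[np.abs(offs) == a].mean() for a in abs_levels])
    return np.arange(len(abs_levels)), values


def reconstruction_slope(curve: np.ndarray, basis: ChannelBasis, *, recentered: bool = True) -> float:
    """Collapse-and-slope statistic of a recentered k-vector."""
    if not recentered:
        raise ValueError("reconstruction_slope requires a recentered curve")
    ranks, values = collapse_curve(curve, basis)
    slope, _ = np.polyfit(ranks, values, 1)
    return float(slope)


def slope_operator(basis: ChannelBasis) -> np.ndarray:
    """Weight vector w with slope(curve) = w @ curve.

    The collapse step and the ordinary-least-squares slope are both linear
    in the curve, so the whole statistic is a fixed linear functional; the
    explicit form lets resampling loops run as one matrix product.
    """
    k = basis.n_channels
    offs = basis.offsets
    abs_levels = np.unique(np.abs(offs))[::-1]
    m = len(abs_levels)
    collapse = np.zeros((m, k))
    for i, a in enumerate(abs_levels):
        members = np.abs(offs) == a
        collapse[i, members] = 1.0 / members.sum()
    ranks = np.arange(m, dtype=float)
    reg = (ranks - ranks.mean()) / np.sum((ranks - ranks.mean()) ** 2)
    return reg @ collapse


@dataclass
class SlopeTest:
    """Bootstrap slope inference for one condition (or a paired difference)."""

    per_subject_slopes: np.ndarray
    point_estimate: float
    boot_distribution: np.ndarray
    p_two_tailed: float
    p_is_bound: bool
    n_boot: int
    seed: int | None

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject_slopes)


def _bootstrap_p(boot_slopes: np.ndarray, n_boot: int):
    """Two-tailed p: 2 * min(frac > 0, frac < 0); all-zero distributions
    report p = 1 (no evidence); an empty side reports the 2/B bound."""
    frac_pos = float(np.mean(boot_slopes > 0))
    frac_neg = float(np.mean(boot_slopes < 0))
    if frac_pos == 0.0 and frac_neg == 0.0:
        return 1.0, False
    p = 2.0 * min(frac_pos, frac_neg)
    if p == 0.0:
        return 2.0 / n_boot, True
    return min(p, 1.0), False


def _resampled_mean_slopes(curves: np.ndarray, w: np.ndarray, n_boot: int, rng):
    n = curves.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    slopes = curves @ w                                  # per-subject slopes
    return slopes[idx].mean(axis=1)


def bootstrap_slope_test(
    per_subject_curves: np.ndarray,
    basis: ChannelBasis,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SlopeTest:
    """Resample subjects with replacement; slope of each resampled mean curve.

    ``per_subject_curves`` is n_subjects × k (recentered).  Averaging
    curves then taking the slope equals averaging slopes, since the
    statistic is linear.
    """
    curves = np.asarray(per_subject_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need >= 2 subjects of recentered curves")
    w = slope_operator(basis)
    rng = np.random.default_rng(seed)
    boot = _resampled_mean_slopes(curves, w, n_boot, rng)
    slopes = curves @ w
    p, bound = _bootstrap_p(boot, n_boot)
    return SlopeTest(
        per_subject_slopes=slopes,
        point_estimate=float(slopes.mean()),
        boot_distribution=boot,
        p_two_tailed=p,
        p_is_bound=bound,
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_difference_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    basis: ChannelBasis,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SlopeTest:
    """Paired bootstrap on slope differences (condition A minus B)."""
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have matching subjects")
    return bootstrap_slope_test(a - b, basis, n_boot=n_boot, seed=seed)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _one_sample_t_power(n: int, d: float, alpha: float, tail: str) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tail == "one":
        crit = sps.t.ppf(1 - alpha, df)
        return float(1 - sps.nct.cdf(crit, df, nc))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float((1 - sps.nct.cdf(crit, df, nc)) + sps.nct.cdf(-crit, df, nc))


def required_sample_size(
    d: float, power: float = 0.90, alpha: float = 0.05, tail: str = "one"
) -> int:
    """Smallest n whose one-sample t test reaches the target power.

    Uses the exact noncentral-t power function (noncentrality d*sqrt(n),
    df n−1); a normal approximation can flip the answer at the boundary.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    for n in range(2, 1_000_001):
        if _one_sample_t_power(n, d, alpha, tail) >= power:
            return n
    raise ValueError("target power unreachable within n <= 1e6")


def paired_permutation_test(
    values_a, values_b, n_perm: int = 10_000, seed: int | None = None
) -> float:
    """Sign-flip permutation test on paired differences; two-tailed p.

    p = proportion of permuted |mean| >= observed |mean|, with the observed
    (identity) permutation included among the n_perm draws.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values must be paired 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm - 1, n))
    perm = np.abs((signs * d).mean(axis=1))
    count = 1 + int(np.sum(perm >= obs - 1e-12))   # identity permutation included
    return count / n_perm


def pearson_correlation(x, y):
    """Product-moment correlation: (r, r_squared, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r**2), float(p)


# Predicted sign of the TR-of-interest reconstruction slope per model, keyed
# (roi, role, item) with role 'content' = location, 'context' = orientation.
# Domain-dependent: engagement follows the feature domain (early visual
# cortex for orientation, IPS for location).  Functional: early visual
# cortex carries content, IPS carries context.  Hybrid: domain-dependent
# plus IPS additionally encoding context regardless of domain.
MODEL_PREDICTIONS = {
    "domain_dependent": {
        ("EVC", "content", "pmi"): "+", ("EVC", "context", "pmi"): "+",
        ("EVC", "content", "umi"): "0", ("EVC", "context", "umi"): "-",
        ("IPS", "content", "pmi"): "+", ("IPS", "context", "pmi"): "0",
        ("IPS", "content", "umi"): "-", ("IPS", "context", "umi"): "0",
    },
    "functional": {
        ("EVC", "content", "pmi"): "+", ("EVC", "context", "pmi"): "0",
        ("EVC", "content", "umi"): "-", ("EVC", "context", "umi"): "0",
        ("IPS", "content", "pmi"): "0", ("IPS", "context", "pmi"): "+",
        ("IPS", "content", "umi"): "0", ("IPS", "context", "umi"): "-",
    },
    "hybrid": {
        ("EVC", "content", "pmi"): "+", ("EVC", "context", "pmi"): "+",
        ("EVC", "content", "umi"): "0", ("EVC", "context", "umi"): "-",
        ("IPS", "content", "pmi"): "+", ("IPS", "context", "pmi"): "+",
        ("IPS", "content", "umi"): "-", ("IPS", "context", "umi"): "-",
    },
}

CELLS = tuple(MODEL_PREDICTIONS["hybrid"].keys())


@dataclass
class ModelAdjudication:
    """Observed sign pattern of the 8 preregistered cells vs each model."""

    observed: dict
    match_counts: dict
    matches: dict = field(default_factory=dict)

    @property
    def best_models(self):
        top = max(self.match_counts.values())
        return sorted(m for m, c in self.match_counts.items() if c == top)

    def to_dict(self) -> dict:
        return {
            "observed": {"|".join(k): v for k, v in self.observed.items()},
            "match_counts": dict(self.match_counts),
            "best_models": self.best_models,
        }


def classify_cell(test: SlopeTest, significant: bool) -> str:
    """'+' / '-' when the slope is significant, '0' otherwise."""
    if not significant:
        return "0"
    return "+" if test.point_estimate > 0 else "-"


def adjudicate_models(
    slope_tests: dict, alpha: float = 0.05, fdr_correct: bool = True
) -> ModelAdjudication:
    """Compare the observed 8-cell sign pattern against the three models.

    ``slope_tests`` maps (roi, role, item) — roi in {'EVC','IPS'}, role in
    {'content','context'}, item in {'pmi','umi'} — to a SlopeTest.
    Significance is assessed at ``alpha``, after BH-FDR across the 8 cells
    unless ``fdr_correct`` is False.
    """
    missing = [c for c in CELLS if c not in slope_tests]
    if missing:
        raise ValueError(f"missing preregistered cells: {missing}")
    ps = np.array([slope_tests[c].p_two_tailed for c in CELLS])
    sig = fdr_bh(ps, q=alpha) if fdr_correct else ps < alpha
    observed = {
        c: classify_cell(slope_tests[c], bool(s)) for c, s in zip(CELLS, sig)
    }
    matches, counts = {}, {}
    for model, table in MODEL_PREDICTIONS.items():
        matches[model] = {c: observed[c] == table[c] for c in CELLS}
        counts[model] = int(sum(matches[model].values()))
    return ModelAdjudication(observed=observed, match_counts=counts, matches=matches)
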