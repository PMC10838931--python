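"""Decision rules and cohort-level metrics for lesion discrimination.

A lesion counts as correctly identified either when the reconstructed
current-density peak is closer to the true lesion's mean vertex
position than to any alternative candidate (peak-distance rule, used
for the uninformed and loose reconstructions), or when the free-energy
difference between the true lesion model and the best alternative is
positive (model-comparison rule, used for the restricted scheme).
Exact ties are scored incorrect - a conservative rule that cannot
inflate performance.

Cohort summaries include percent correct with percentile-bootstrap
confidence intervals (resampling lesions), the closed-form chance
level of uniform guessing (n_patients / n_lesions), equal-occupancy
distance-binned performance, and the mode/percentile summary of the
ΔF distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "is_correct_peak",
    "is_correct_comparison",
    "percent_correct",
    "chance_level",
    "distance_binned_performance",
    "delta_f_summary",
    "nearest_alternative_distances",
]


def is_correct_peak(peak_position, true_mean, other_means) -> bool:
    """Peak-distance rule: correct iff the true lesion's mean vertex
    position is the unique nearest among all candidates."""
    other_means = np.atleast_2d(np.asarray(other_means, dtype=np.float64))
    if len(other_means) < 1:
        raise ValueError("need at least one alternative lesion")
    peak_position = np.asarray(peak_position, dtype=np.float64)
    d_true = float(np.linalg.norm(peak_position - np.asarray(true_mean)))
    d_others = np.linalg.norm(other_means - peak_position, axis=1)
    return bool(d_true < d_others.min())


def is_correct_comparison(comparison) -> bool:
    """Model-comparison rule: correct iff ΔF > 0 (ties incorrect)."""
    delta_f = comparison.delta_f if hasattr(comparison, "delta_f") else comparison
    if delta_f is None:
        raise ValueError("comparison has no defined ΔF (truth unknown)")
    return bool(delta_f > 0)


def _bootstrap_ci(values, n_boot, rng, level=95.0):
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    stats = values[idx].mean(axis=1) * 100.0
    lo, hi = np.percentile(stats, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


def percent_correct(
    table: pd.DataFrame,
    by=None,
    n_boot: int = 2000,
    seed: int = 0,
    correct_col: str = "correct",
) -> pd.DataFrame:
    """Percent correct per group with percentile-bootstrap 95% CIs.

    ``table`` needs a boolean ``correct`` column; resampling is at the
    row (= lesion outcome) level within each group.
    """
    rng = np.random.default_rng(seed)
    groups = [((), table)] if by is None else list(table.groupby(by, sort=True))
    rows = []
    keys = [] if by is None else ([by] if isinstance(by, str) else list(by))
    for key, grp in groups:
        vals = grp[correct_col].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        pc = float(vals.mean() * 100.0)
        lo, hi = _bootstrap_ci(vals, n_boot, rng)
        rec = dict(
            zip(keys, key if isinstance(key, tuple) else (key,))
        )
        rec.update(
            {"n": len(vals), "percent_correct": pc, "ci_low": lo, "ci_high": hi}
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def chance_level(cohort, n_mc: int = 100_000, seed: int = 0):
    """Expected percent correct under uniform guessing among each
    patient's candidates.

    A patient with k lesions contributes k simulated lesions, each
    guessed correctly with probability 1/k, so the closed form is
    n_patients / n_lesions x 100.  The CI comes from a Monte-Carlo
    guessing simulation over the whole cohort.
    """
    ks = np.array([p.k for p in cohort.patients])
    if np.any(ks < 2):
        raise ValueError("every patient must have at least 2 candidate lesions")
    n_lesions = int(ks.sum())
    point = 100.0 * len(ks) / n_lesions
    rng = np.random.default_rng(seed)
    # each lesion of a k-lesion patient: Bernoulli(1/k)
    probs = np.repeat(1.0 / ks, ks)
    draws = rng.random((n_mc, n_lesions)) < probs[None, :]
    rates = draws.mean(axis=1) * 100.0
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return point, (float(lo), float(hi))


def nearest_alternative_distances(patient) -> np.ndarray:
    """Per-lesion distance (mm) to the nearest alternative candidate COM."""
    coms = patient.com_positions()
    d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def distance_binned_performance(
    table: pd.DataFrame,
    n_bins: int = 4,
    n_boot: int = 2000,
    seed: int = 0,
    distance_col: str = "nearest_alt_mm",
) -> pd.DataFrame:
    """Percent correct in equal-occupancy bins of nearest-alternative
    distance, with bootstrap CIs resampled within each bin."""
    if n_bins > len(table):
        raise ValueError("more bins than lesions")
    d = table[distance_col].to_numpy(dtype=float)
    order = np.argsort(d, kind="stable")
    # equal-count assignment: bin sizes differ by at most one
    bins = np.empty(len(d), dtype=int)
    bins[order] = (np.arange(len(d)) * n_bins) // len(d)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bins):
        sel = bins == b
        vals = table.loc[sel, "correct"].to_numpy(dtype=float)
        dd = d[sel]
        lo, hi = _bootstrap_ci(vals, n_boot, rng)
        rows.append(
            {
                "bin": b,
                "center_mm": float((dd.min() + dd.max()) / 2.0),
                "min_mm": float(dd.min()),
                "max_mm": float(dd.max()),
                "n": int(sel.sum()),
                "percent_correct": float(vals.mean() * 100.0),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def delta_f_summary(delta_f, bin_width: float = None) -> dict:
    """Histogram-mode bin centre and 5th/95th percentiles of ΔF."""
    delta_f = np.asarray(delta_f, dtype=float)
    delta_f = delta_f[np.isfinite(delta_f)]
    if delta_f.size == 0:
        raise ValueError("no ΔF values")
    p5, p95 = np.percentile(delta_f, [5.0, 95.0])
    if delta_f.size == 1 or np.ptp(delta_f) == 0:
        mode = float(delta_f[0])
    else:
        if bin_width is None:
            # Freedman-Diaconis with a sane fallback
            iqr = np.subtract(*np.percentile(delta_f, [75, 25]))
            bin_width = (
                2.0 * iqr / len(delta_f) ** (1.0 / 3.0)
                if iqr > 0
                else np.ptp(delta_f) / 10.0
            )
        edges = np.arange(
            delta_f.min(), delta_f.max() + bin_width, bin_width
        )
        counts, edges = np.histogram(delta_f, bins=edges)
        i = int(np.argmax(counts))
        mode = float((edges[i] + edges[i + 1]) / 2.0)
    return {"mode": mode, "p5": float(p5), "p95": float(p95)}
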