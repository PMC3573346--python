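"""ROC/AUC computation, error rates, and the simulation benchmark harness.

The harness replicates the evaluation design used to compare phase-locking
detectors: repeated simulations produce "positive" recordings (a set of
phase-locked trials plus an unlocked baseline) and "negative" recordings
(unlocked trials only), each method yields one detection statistic per ROI
pair per simulation, statistics are pooled into per-method ROC curves, and
AUC error bounds come from splitting the iterations into replicate sets.
For p-value-producing methods (USTPL, PLV) the ROC statistic is -p (more
significant = larger); PLI and PBI enter through their raw statistic
magnitudes, since they carry no analytic significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circstats import AngleSample, plv, rayleigh_pvalue
from .exceptions import InvalidInputError, UnsupportedMethodError
from .indices import pbi, pli
from .ranktest import TestResult, ustpl_test
from .simulate import CrosstalkModel, SimulationConfig, make_crosstalk_model, simulate_recording
from .spectral import morlet_coefficients, phase_differences

__all__ = [
    "ROCResult",
    "BenchmarkGrid",
    "roc_curve",
    "classification_rate",
    "error_rate",
    "significance_detections",
    "n_roi_pairs",
    "run_benchmark",
]

KNOWN_METHODS = ("USTPL", "PLV", "PLI", "PBI")


@dataclass(frozen=True)
class ROCResult:
    """An ROC curve: ordered (FPR, TPR) points from (0,0) to (1,1) with trapezoidal AUC."""

    points: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    auc_sd: Optional[float] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        p.setflags(write=False)
        object.__setattr__(self, "points", p)


@dataclass(frozen=True)
class BenchmarkGrid:
    """The benchmark condition grid and iteration bookkeeping.

    ``n_replicate_sets`` x ``iterations_per_set`` simulations are run per
    condition for positives and again for negatives; each set yields one
    ROC curve, and the AUC is reported as mean +/- sd across sets.
    """

    methods: tuple = KNOWN_METHODS[:3] + ("PBI",)
    noise_levels: tuple = (0.001,)
    n_trials: tuple = (20,)
    kappas: tuple = (50.0,)
    n_replicate_sets: int = 5
    iterations_per_set: int = 4
    n_iterations_pos: Optional[int] = None
    n_iterations_neg: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("methods", "noise_levels", "n_trials", "kappas"):
            seq = tuple(getattr(self, name))
            if len(seq) == 0:
                raise InvalidInputError(f"{name} must be non-empty")
            object.__setattr__(self, name, seq)
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise InvalidInputError(f"unknown methods {sorted(unknown)}; choose from {KNOWN_METHODS}")
        if self.n_replicate_sets < 1 or self.iterations_per_set < 1:
            raise InvalidInputError("iteration counts must be >= 1")
        total = self.n_replicate_sets * self.iterations_per_set
        for name in ("n_iterations_pos", "n_iterations_neg"):
            val = getattr(self, name)
            if val is None:
                object.__setattr__(self, name, total)
            elif val != total:
                raise InvalidInputError(
                    f"{name}={val} inconsistent with {self.n_replicate_sets} sets x "
                    f"{self.iterations_per_set} iterations = {total}"
                )


def roc_curve(
    pos_stats: Sequence[float],
    neg_stats: Sequence[float],
    higher_is_significant: bool = True,
) -> ROCResult:
    """ROC curve from pooled detection statistics.

    Every distinct observed statistic serves as a threshold; a value equal
    to or more significant than the threshold counts as a detected
    positive. Endpoints (0,0) and (1,1) are appended and the AUC is the
    trapezoidal integral, which equals the Mann-Whitney probability with
    ties counted 1/2.
    """
    pos = np.asarray(pos_stats, dtype=float)
    neg = np.asarray(neg_stats, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("pos_stats and neg_stats must both be non-empty")
    for name, arr in (("pos_stats", pos), ("neg_stats", neg)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise InvalidInputError(f"non-finite statistic in {name} at index {int(bad[0])}")
    if not higher_is_significant:
        pos, neg = -pos, -neg
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tpr = (pos.size - np.searchsorted(pos_sorted, thresholds, side="left")) / pos.size
    fpr = (neg.size - np.searchsorted(neg_sorted, thresholds, side="left")) / neg.size
    fpr_pts = np.concatenate([[0.0], fpr])
    tpr_pts = np.concatenate([[0.0], tpr])
    if fpr_pts[-1] != 1.0 or tpr_pts[-1] != 1.0:  # defensive; lowest threshold admits all
        fpr_pts = np.concatenate([fpr_pts, [1.0]])
        tpr_pts = np.concatenate([tpr_pts, [1.0]])
    auc = float(np.trapezoid(tpr_pts, fpr_pts))
    return ROCResult(
        points=np.column_stack([fpr_pts, tpr_pts]),
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def classification_rate(detections: Sequence[bool], truth: Sequence[bool]) -> float:
    """(TP + TN) / (P + N): the proportion of correctly classified tests."""
    det = np.asarray(detections, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if det.shape != tru.shape or det.size < 1:
        raise InvalidInputError("detections and truth must be equal-length, non-empty")
    return float(np.mean(det == tru))


def error_rate(detections: Sequence[bool], truth: Sequence[bool]) -> float:
    """1 - classification_rate: the proportion of misclassified tests."""
    return 1.0 - classification_rate(detections, truth)


def significance_detections(
    results: Sequence[TestResult],
    alpha: float = 0.05,
    bonferroni_m: Optional[int] = None,
) -> np.ndarray:
    """Threshold p-values at ``alpha`` (divided by ``bonferroni_m`` when given)."""
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must lie in (0, 1)")
    threshold = alpha / bonferroni_m if bonferroni_m else alpha
    out = np.empty(len(results), dtype=bool)
    for i, r in enumerate(results):
        if r.p_value is None:
            raise UnsupportedMethodError(
                f"result {i} ({r.method}) carries no p-value; use the permutation "
                f"significance wrappers (pli_significance / pbi_significance) first"
            )
        out[i] = r.p_value < threshold
    return out


def n_roi_pairs(n_rois: int) -> int:
    """Number of simultaneous pairwise comparisons among ``n_rois`` regions."""
    return n_rois * (n_rois - 1) // 2


def _pair_statistics(config: SimulationConfig, model: CrosstalkModel, methods, cycles: float = 7.0):
    """One simulation -> per-method detection statistics (and p-values) per ROI pair.

    The "stim" population is the phase-locked trials when present; for null
    (negative) recordings with no locked trials, the unlocked trials are
    split in half into surrogate baseline and stim populations.
    """
    observed, plan, _ = simulate_recording(config, model=model)
    t_eval = observed.t0 + observed.duration / 2.0
    coeffs = morlet_coefficients(observed, config.carrier_freq, t_eval, cycles=cycles)
    if plan.is_locked.any():
        stim_idx = np.flatnonzero(plan.is_locked)
        base_idx = np.flatnonzero(~plan.is_locked)
    else:
        half = plan.n_trials // 2
        base_idx = np.arange(half)
        stim_idx = np.arange(half, plan.n_trials)
    stats: dict[str, list[float]] = {m: [] for m in methods}
    pvals: dict[str, list[float]] = {m: [] for m in methods if m in ("USTPL", "PLV")}
    for a in range(config.n_rois):
        for b in range(a + 1, config.n_rois):
            phases = phase_differences(coeffs, a, b).angles
            stim = AngleSample(phases[stim_idx], label="stim")
            base = AngleSample(phases[base_idx], label="baseline")
            if "USTPL" in methods:
                res = ustpl_test(stim, base, mode="asymptotic")
                stats["USTPL"].append(-res.p_value)
                pvals["USTPL"].append(res.p_value)
            if "PLV" in methods:
                p = rayleigh_pvalue(plv(stim), stim.n)
                stats["PLV"].append(-p)
                pvals["PLV"].append(p)
            if "PLI" in methods:
                stats["PLI"].append(pli(stim))
            if "PBI" in methods:
                stats["PBI"].append(abs(pbi(base, stim)))
    return stats, pvals


def run_benchmark(
    grid: BenchmarkGrid,
    sim_config_base: SimulationConfig,
    model: Optional[CrosstalkModel] = None,
    null_positives: bool = False,
) -> pd.DataFrame:
    """Run the full benchmark grid and tabulate per-method AUC and error rates.

    For each (noise level, trial count, kappa) condition the harness runs
    ``n_replicate_sets * iterations_per_set`` positive and as many negative
    simulations through one fixed crosstalk model (the "anatomy" of the
    run), pools each method's statistics within each replicate set into an
    ROC curve, and reports the AUC mean and sd across sets. For USTPL and
    PLV it additionally reports classification/error rates at alpha = 0.05
    with and without Bonferroni correction over the ROI-pair count.

    ``model`` overrides the internally drawn crosstalk model (the fixed
    "anatomy" of the run); ``null_positives=True`` generates the positive
    simulations from the unlocked generator too, a calibration mode whose
    AUC should sit at chance for every method.
    """
    seeder = np.random.default_rng(grid.seed)
    if model is None:
        model = make_crosstalk_model(
            sim_config_base.n_rois,
            sim_config_base.crosstalk_strength,
            seed=int(seeder.integers(0, 2**31)),
        )
    elif model.n_rois != sim_config_base.n_rois:
        raise InvalidInputError("supplied model ROI count does not match the base config")
    m_pairs = n_roi_pairs(sim_config_base.n_rois)
    rows = []
    for noise in grid.noise_levels:
        for nt in grid.n_trials:
            for kappa in grid.kappas:
                per_set_stats = {m: {"pos": [[] for _ in range(grid.n_replicate_sets)],
                                     "neg": [[] for _ in range(grid.n_replicate_sets)]}
                                 for m in grid.methods}
                pooled_p = {m: {"pos": [], "neg": []} for m in grid.methods if m in ("USTPL", "PLV")}
                for s in range(grid.n_replicate_sets):
                    for _ in range(grid.iterations_per_set):
                        cfg_pos = replace(
                            sim_config_base, noise_level=noise, kappa=kappa,
                            n_trials_locked=0 if null_positives else nt,
                            n_trials_unlocked=2 * nt if null_positives else nt,
                            seed=int(seeder.integers(0, 2**31)),
                        )
                        cfg_neg = replace(
                            sim_config_base, noise_level=noise, kappa=kappa,
                            n_trials_locked=0, n_trials_unlocked=2 * nt,
                            seed=int(seeder.integers(0, 2**31)),
                        )
                        for label, cfg in (("pos", cfg_pos), ("neg", cfg_neg)):
                            stats, pvals = _pair_statistics(cfg, model, grid.methods)
                            for m in grid.methods:
                                per_set_stats[m][label][s].extend(stats[m])
                                if m in pooled_p:
                                    pooled_p[m][label].extend(pvals[m])
                for m in grid.methods:
                    aucs = [
                        roc_curve(per_set_stats[m]["pos"][s], per_set_stats[m]["neg"][s]).auc
                        for s in range(grid.n_replicate_sets)
                    ]
                    row = {
                        "method": m, "noise_level": noise, "n_trials": nt, "kappa": kappa,
                        "auc": float(np.mean(aucs)), "auc_sd": float(np.std(aucs, ddof=1)),
                        "correct_rate_unc": np.nan, "error_rate_unc": np.nan,
                        "correct_rate_bonf": np.nan, "error_rate_bonf": np.nan,
                    }
                    if m in pooled_p:
                        p_all = np.array(pooled_p[m]["pos"] + pooled_p[m]["neg"])
                        truth = np.concatenate([
                            np.ones(len(pooled_p[m]["pos"]), bool),
                            np.zeros(len(pooled_p[m]["neg"]), bool),
                        ])
                        det_unc = p_all < 0.05
                        det_bonf = p_all < 0.05 / m_pairs
                        row["correct_rate_unc"] = classification_rate(det_unc, truth)
                        row["error_rate_unc"] = error_rate(det_unc, truth)
                        row["correct_rate_bonf"] = classification_rate(det_bonf, truth)
                        row["error_rate_bonf"] = error_rate(det_bonf, truth)
                    rows.append(row)
    return pd.DataFrame(rows)
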