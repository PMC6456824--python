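"""Cohort-level aggregation of per-subject effects.

All uncertainty statements here come from resampling subjects with
replacement (the subject, not the day, is the sampling unit): the mean
personal effect and its bootstrap SD and percentile interval, the paired
direction comparison, the per-group contrasts against the control group,
and the history-depth (T) sweep that re-runs matching with progressively
longer mood/sleep histories as confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import LaggedDataset, SubjectPanel, build_lagged_dataset
from .psm import PSMConfig, cohort_personal_effects

__all__ = [
    "BootstrapSummary", "Contrast", "TSweepResult",
    "bootstrap_mean_effect", "compare_directions_psm",
    "group_contrasts", "run_T_sweep",
]


@dataclass
class BootstrapSummary:
    direction: str
    T: int
    group: str
    n_boot: int
    seed: int
    mean_effect: float
    sd_effect: float
    ci_low: float
    ci_high: float
    n_subjects: int
    matched: bool = True

    def to_dict(self) -> dict:
        return {
            "direction": self.direction, "T": self.T, "group": self.group,
            "matched": self.matched, "mean_effect": self.mean_effect,
            "sd_effect": self.sd_effect, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_subjects": self.n_subjects,
            "n_boot": self.n_boot,
        }

    def overlaps(self, other: "BootstrapSummary") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


@dataclass
class Contrast:
    left: str
    right: str
    direction: str
    difference: float
    p_value: float
    boot_sd: float
    n_boot: int
    warning: str = ""

    def to_dict(self) -> dict:
        return {"left": self.left, "right": self.right,
                "direction": self.direction, "difference": self.difference,
                "p": self.p_value, "boot_sd": self.boot_sd,
                "n_boot": self.n_boot, "warning": self.warning}


def _valid_effects(effects: pd.DataFrame) -> pd.DataFrame:
    return effects[effects["effect"].notna()]


def _percentile_p(diffs: np.ndarray) -> float:
    n = len(diffs)
    lo = (np.sum(diffs <= 0.0) + 1) / (n + 1)
    hi = (np.sum(diffs >= 0.0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def bootstrap_mean_effect(effects: pd.DataFrame, n_boot: int = 100,
                          seed: int = 0, group: str = "all") -> BootstrapSummary:
    """Bootstrap (over subjects) the cohort mean personal effect.

    ``effects`` is a per-subject table as produced by
    :func:`sleepmood.psm.cohort_personal_effects`; rows without a valid
    effect are ignored (their exclusion is already on record there).
    """
    valid = _valid_effects(effects)
    if group != "all":
        valid = valid[valid["group"] == group]
    vals = valid["effect"].to_numpy(float)
    if len(vals) < 2:
        raise ValueError(f"need >=2 valid subjects for group {group!r}, got {len(vals)}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    direction = str(effects["direction"].iloc[0])
    T = int(effects["T"].iloc[0])
    matched = bool(effects["matched"].iloc[0])
    return BootstrapSummary(
        direction=direction, T=T, group=group, n_boot=n_boot, seed=seed,
        mean_effect=float(vals.mean()), sd_effect=float(boot_means.std(ddof=1)),
        ci_low=float(lo), ci_high=float(hi), n_subjects=len(vals), matched=matched,
    )


def compare_directions_psm(effects_a: pd.DataFrame, effects_b: pd.DataFrame,
                           n_boot: int = 100, seed: int = 0) -> Contrast:
    """Bootstrap test of the mean-effect difference between directions.

    Subjects valid in both directions are resampled jointly (paired); if
    the two tables share no subjects the comparison falls back to
    independent resampling and says so in ``warning``.
    """
    a = _valid_effects(effects_a).set_index("subject_id")["effect"]
    b = _valid_effects(effects_b).set_index("subject_id")["effect"]
    if len(a) < 2 or len(b) < 2:
        return Contrast(
            left=str(effects_a["direction"].iloc[0]),
            right=str(effects_b["direction"].iloc[0]),
            direction="difference", difference=float("nan"),
            p_value=float("nan"), boot_sd=float("nan"), n_boot=n_boot,
            warning="skipped: fewer than 2 valid subjects in an arm")
    common = a.index.intersection(b.index)
    rng = np.random.default_rng(seed)
    warning = ""
    if len(common) >= 2:
        diff_per_subject = (a.loc[common] - b.loc[common]).to_numpy(float)
        idx = rng.integers(0, len(diff_per_subject), size=(n_boot, len(diff_per_subject)))
        diffs = diff_per_subject[idx].mean(axis=1)
        point = float(diff_per_subject.mean())
    else:
        warning = "disjoint subject sets: unpaired bootstrap"
        va, vb = a.to_numpy(float), b.to_numpy(float)
        ia = rng.integers(0, len(va), size=(n_boot, len(va)))
        ib = rng.integers(0, len(vb), size=(n_boot, len(vb)))
        diffs = va[ia].mean(axis=1) - vb[ib].mean(axis=1)
        point = float(va.mean() - vb.mean())
    return Contrast(
        left=str(effects_a["direction"].iloc[0]),
        right=str(effects_b["direction"].iloc[0]),
        direction="difference", difference=point,
        p_value=_percentile_p(diffs), boot_sd=float(np.std(diffs, ddof=1)),
        n_boot=n_boot, warning=warning,
    )


def group_contrasts(effects: pd.DataFrame, n_boot: int = 100, seed: int = 0,
                    reference: str = "control") -> list[Contrast]:
    """Contrast each symptom group's mean effect against the reference group.

    Groups contain different subjects, so resampling is independent
    (unpaired) within each group.  Groups with fewer than two valid
    subjects are skipped with a flagged placeholder contrast.
    """
    valid = _valid_effects(effects)
    direction = str(effects["direction"].iloc[0])
    ref_vals = valid[valid["group"] == reference]["effect"].to_numpy(float)
    out = []
    rng = np.random.default_rng(seed)
    groups = [g for g in valid["group"].unique() if g != reference]
    for g in sorted(groups):
        gv = valid[valid["group"] == g]["effect"].to_numpy(float)
        if len(gv) < 2 or len(ref_vals) < 2:
            out.append(Contrast(g, reference, direction, float("nan"),
                                float("nan"), float("nan"), n_boot,
                                warning="skipped: group too small"))
            continue
        ig = rng.integers(0, len(gv), size=(n_boot, len(gv)))
        ir = rng.integers(0, len(ref_vals), size=(n_boot, len(ref_vals)))
        diffs = gv[ig].mean(axis=1) - ref_vals[ir].mean(axis=1)
        out.append(Contrast(g, reference, direction,
                            float(gv.mean() - ref_vals.mean()),
                            _percentile_p(diffs), float(np.std(diffs, ddof=1)),
                            n_boot))
    return out


@dataclass
class TSweepResult:
    direction: str
    unmatched: BootstrapSummary
    matched: dict[int, BootstrapSummary]
    exclusions: dict[str, dict[str, int]] = field(default_factory=dict)
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summaries(self) -> list[BootstrapSummary]:
        return [self.unmatched] + [self.matched[t] for t in sorted(self.matched)]


def _exclusion_counts(effects: pd.DataFrame) -> dict[str, int]:
    reasons = effects["excluded_reason"].dropna()
    out = {r: int(c) for r, c in reasons.value_counts().items()}
    out["valid"] = int(effects["effect"].notna().sum())
    return out


def run_T_sweep(panels: list[SubjectPanel], direction: str,
                T_values=(0, 1, 2, 3), config: PSMConfig | None = None,
                n_boot: int = 100, seed: int = 0) -> TSweepResult:
    """Unmatched effect plus matched effects at each history depth T.

    Rows per subject shrink as T grows (each extra lag needs one more
    consecutive prior day), so per-T exclusion counts are part of the
    result rather than an error.
    """
    config = config or PSMConfig()
    base = build_lagged_dataset(panels, direction, T=0)
    eff_un = cohort_personal_effects(panels, base, config, matched=False)
    result = TSweepResult(
        direction=direction,
        unmatched=_summary_or_placeholder(eff_un, n_boot, seed),
        matched={},
        exclusions={"unmatched": _exclusion_counts(eff_un)},
        effects={"unmatched": eff_un},
    )
    for T in T_values:
        ds = base if T == 0 else build_lagged_dataset(panels, direction, T=T)
        cfg = PSMConfig(history_depth=T, match_ratio=config.match_ratio,
                        caliper=config.caliper,
                        with_replacement=config.with_replacement,
                        tie_rule=config.tie_rule, ridge_c=config.ridge_c,
                        seed=config.seed)
        eff = cohort_personal_effects(panels, ds, cfg, matched=True)
        result.effects[f"T{T}"] = eff
        result.exclusions[f"T{T}"] = _exclusion_counts(eff)
        result.matched[T] = _summary_or_placeholder(eff, n_boot, seed + 1 + T)
    return result


def _summary_or_placeholder(effects: pd.DataFrame, n_boot: int,
                            seed: int) -> BootstrapSummary:
    """Summarize, or report an all-NaN summary when near-universal
    exclusion leaves fewer than two valid subjects (not an error: the
    exclusion ledger carries the explanation)."""
    try:
        return bootstrap_mean_effect(effects, n_boot=n_boot, seed=seed)
    except ValueError:
        nan = float("nan")
        return BootstrapSummary(
            direction=str(effects["direction"].iloc[0]),
            T=int(effects["T"].iloc[0]), group="all", n_boot=n_boot, seed=seed,
            mean_effect=nan, sd_effect=nan, ci_low=nan, ci_high=nan,
            n_subjects=int(effects["effect"].notna().sum()),
            matched=bool(effects["matched"].iloc[0]),
        )
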