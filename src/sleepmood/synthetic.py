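"""Synthetic EMA cohorts with known cross-lagged sleep-mood dynamics.

The generator emulates a six-week mobile-phone diary study: four symptom
groups defined by PHQ-9/GAD-7 screening cutoffs, one sleep-quality rating
each morning and three ratings per day of mood, stress, energy and focus,
all on 0-8 Likert scales, plus exogenous daily covariates (physical
activity minutes, weather, day of week, day type).

The latent day-level dynamics are a bivariate linear system.  Writing
``s(t)`` for the latent quality of the night ending on the morning of day
``t`` and ``m(t)`` for the latent mood of day ``t``::

    m(t)   = ar_mood  * m(t-1) + beta_sleep_to_mood * s(t) + g * c(t)   + e_m(t)
    s(t+1) = ar_sleep * s(t)   + beta_mood_to_sleep * m(t) + g * c(t)   + e_s(t+1)

with ``c(t)`` a shared standard-normal daily confounder (``g`` is
``confounder_strength``) and independent N(0, noise_sd^2) innovations.
``c(t)`` is also emitted, with independent noise, as the observable
stress/energy/focus ratings of day ``t`` — so the measured covariates of
the day before the outcome carry the confounding signal, as a matching
analysis requires.

Latent values reach the questionnaire through a subject-specific affine
reporting style followed by ordinalization::

    observed = clip(round_half_up(4 + scale * latent + shift), 0, 8)

Within-person z-scoring removes the affine style exactly on the latent
scale; on the observed scale it removes it up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import CONSTRUCTS, LIKERT_MAX, SubjectPanel, aggregate_daily, write_panel_csv

__all__ = [
    "SimConfig",
    "GroupLabel",
    "ReportingStyle",
    "GROUP_NAMES",
    "SCREENING_DISTRIBUTIONS",
    "simulate_cohort",
    "simulate_subject",
    "inject_missingness",
    "write_truth_yaml",
]

GROUP_NAMES = ("control", "depressed", "anxious", "depressed_anxious")

#: screening-score means/SDs per group (PHQ-9 0-27, GAD-7 0-21), matching the
#: study design the generator emulates; scores are rejection-sampled to
#: satisfy the cutoff-10 group definitions.
SCREENING_DISTRIBUTIONS = {
    "control": {"phq9": (4.47, 3.05), "gad7": (3.80, 2.95)},
    "depressed": {"phq9": (13.40, 2.90), "gad7": (5.94, 2.43)},
    "anxious": {"phq9": (7.11, 1.69), "gad7": (13.36, 2.88)},
    "depressed_anxious": {"phq9": (14.19, 3.45), "gad7": (14.33, 3.06)},
}

PHQ9_MAX, GAD7_MAX, CUTOFF = 27, 21, 10

# measurement-layer constants: SD of the noise on each of the three
# within-day ratings, and SD of the construct-specific noise with which
# stress/energy/focus reflect the shared daily confounder
REPORT_NOISE_SD = 0.5
PROXY_NOISE_SD = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults emulate the target study: four groups of ~51 subjects
    followed for 42 planned days, moderate day-to-day carryover, a
    sleep-to-mood coupling substantially larger than the reverse, a
    moderate shared daily confounder, and ~10% missing days.
    """

    n_subjects_per_group: int = 51
    n_days: int = 42
    beta_sleep_to_mood: float = 0.4
    beta_mood_to_sleep: float = 0.1
    ar_mood: float = 0.3
    ar_sleep: float = 0.1
    confounder_strength: float = 0.3
    noise_sd: float = 1.0
    missing_prob: float = 0.1
    seed: int = 0
    #: optional per-group overrides of the cross-lag coefficients, e.g.
    #: ``{"anxious": {"beta_mood_to_sleep": 0.2}}`` — groups differing in
    #: coupling strength are part of the emulated study design
    group_betas: dict | None = None

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group: must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days: must be >= 1")
        for name in ("ar_mood", "ar_sleep"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}: must be in [0, 1)")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob: must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be >= 0")
        if self.group_betas is not None:
            for g, over in self.group_betas.items():
                if g not in GROUP_NAMES:
                    raise ValueError(f"group_betas: unknown group {g!r}")
                bad = set(over) - {"beta_sleep_to_mood", "beta_mood_to_sleep"}
                if bad:
                    raise ValueError(
                        f"group_betas: unknown field(s) {sorted(bad)} for group {g!r}")


@dataclass(frozen=True)
class GroupLabel:
    """Symptom-group membership derived from the two screening scores."""

    name: str
    phq9: int
    gad7: int

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"name: unknown group {self.name!r}")
        if not (0 <= self.phq9 <= PHQ9_MAX):
            raise ValueError("phq9: out of range")
        if not (0 <= self.gad7 <= GAD7_MAX):
            raise ValueError("gad7: out of range")
        expected = _group_of(self.phq9, self.gad7)
        if expected != self.name:
            raise ValueError(
                f"name: scores phq9={self.phq9}, gad7={self.gad7} imply "
                f"{expected!r}, not {self.name!r}"
            )


@dataclass(frozen=True)
class ReportingStyle:
    """Subject-specific affine response style on the Likert mapping."""

    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale: must be > 0")


def _group_of(phq9: int, gad7: int) -> str:
    if phq9 >= CUTOFF and gad7 >= CUTOFF:
        return "depressed_anxious"
    if phq9 >= CUTOFF:
        return "depressed"
    if gad7 >= CUTOFF:
        return "anxious"
    return "control"


def _sample_screening(group: str, rng: np.random.Generator) -> GroupLabel:
    # truncated-normal scores via rejection, so the cutoff invariant holds
    dist = SCREENING_DISTRIBUTIONS[group]
    while True:
        phq9 = int(np.clip(round(rng.normal(*dist["phq9"])), 0, PHQ9_MAX))
        gad7 = int(np.clip(round(rng.normal(*dist["gad7"])), 0, GAD7_MAX))
        if _group_of(phq9, gad7) == group:
            return GroupLabel(group, phq9, gad7)


def _likert(latent: np.ndarray, style: ReportingStyle) -> np.ndarray:
    """Affine style then round-half-up then clip to the 0-8 scale."""
    raw = 4.0 + style.scale * np.asarray(latent, dtype=float) + style.shift
    return np.clip(np.floor(raw + 0.5), 0, LIKERT_MAX)


def simulate_subject(
    style: ReportingStyle,
    group: GroupLabel,
    config: SimConfig,
    subject_seed: int,
    subject_id: str = "S000",
) -> SubjectPanel:
    """Simulate one subject's complete (gap-free) daily panel.

    The returned panel's ``meta`` carries the latent series and the
    ground-truth parameters so recovery can be checked downstream.
    """
    rng = np.random.default_rng(subject_seed)
    n = config.n_days
    g = config.confounder_strength

    c = rng.normal(0.0, 1.0, n)
    e_m = rng.normal(0.0, config.noise_sd, n)
    e_s = rng.normal(0.0, config.noise_sd, n)

    m = np.zeros(n)
    s = np.zeros(n)
    s[0] = e_s[0]
    for t in range(n):
        if t > 0:
            s[t] = (config.ar_sleep * s[t - 1]
                    + config.beta_mood_to_sleep * m[t - 1]
                    + g * c[t - 1] + e_s[t])
        prev_m = m[t - 1] if t > 0 else 0.0
        m[t] = (config.ar_mood * prev_m
                + config.beta_sleep_to_mood * s[t]
                + g * c[t] + e_m[t])

    rec = pd.DataFrame({"day_index": np.arange(1, n + 1)})
    dow_start = int(rng.integers(0, 7))
    rec["day_of_week"] = ((rec["day_index"] - 1 + dow_start) % 7) + 1
    weekend = rec["day_of_week"] >= 6
    u = rng.random(n)
    day_type = np.where(
        weekend,
        np.where(u < 0.8, "off", np.where(u < 0.9, "partial", "normal")),
        np.where(u < 0.85, "normal", np.where(u < 0.95, "partial", "off")),
    )
    rec["day_type"] = day_type
    rec["sleep_quality"] = _likert(s, style)

    construct_latent = {"mood": m}
    for name in ("stress", "energy", "focus"):
        construct_latent[name] = c + rng.normal(0.0, PROXY_NOISE_SD, n)
    for name in CONSTRUCTS:
        base = construct_latent[name]
        for j in (1, 2, 3):
            rec[f"{name}_{j}"] = _likert(
                base + rng.normal(0.0, REPORT_NOISE_SD, n), style
            )
        rec[name] = [
            aggregate_daily(row)
            for row in rec[[f"{name}_{j}" for j in (1, 2, 3)]].to_numpy()
        ]

    # exogenous covariates, independent of the latent dynamics
    rec["activity_minutes"] = np.round(rng.gamma(2.0, 20.0, n), 1)
    temp_base = rng.normal(12.0, 6.0)
    rec["mean_temp"] = np.round(temp_base + rng.normal(0.0, 5.0, n), 1)
    rec["clear_sky_minutes"] = np.round(np.clip(rng.normal(300.0, 150.0, n), 0, 720), 0)

    meta = {
        "style": asdict(style),
        "subject_seed": int(subject_seed),
        "truth": {
            "beta_sleep_to_mood": config.beta_sleep_to_mood,
            "beta_mood_to_sleep": config.beta_mood_to_sleep,
            "ar_mood": config.ar_mood,
            "ar_sleep": config.ar_sleep,
            "confounder_strength": g,
        },
        "latent_mood": m,
        "latent_sleep": s,
        "confounder": c,
    }
    return SubjectPanel(
        subject_id=subject_id,
        group=group.name,
        phq9=group.phq9,
        gad7=group.gad7,
        records=rec,
        meta=meta,
    )


def simulate_cohort(config: SimConfig) -> list[SubjectPanel]:
    """Simulate the full four-group cohort, including missing days.

    Seeds fan out from ``config.seed`` through a ``SeedSequence`` so that
    identical configs produce bit-identical cohorts.
    """
    import dataclasses as _dc

    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    panels = []
    idx = 0
    for group_name in GROUP_NAMES:
        group_config = config
        if config.group_betas and group_name in config.group_betas:
            group_config = _dc.replace(config, group_betas=None,
                                       **config.group_betas[group_name])
        for _ in range(config.n_subjects_per_group):
            idx += 1
            sid = f"S{idx:03d}"
            group = _sample_screening(group_name, cohort_rng)
            style = ReportingStyle(
                shift=float(cohort_rng.normal(0.0, 0.8)),
                scale=float(cohort_rng.uniform(0.7, 1.3)),
            )
            subject_seed = int(cohort_rng.integers(0, 2**31 - 1))
            panel = simulate_subject(style, group, group_config, subject_seed, sid)
            if config.missing_prob > 0:
                panel = inject_missingness(
                    panel, config.missing_prob,
                    seed=int(cohort_rng.integers(0, 2**31 - 1)),
                )
            panels.append(panel)
    return panels


def inject_missingness(panel: SubjectPanel, missing_prob: float, seed: int) -> SubjectPanel:
    """Drop each day independently with probability ``missing_prob`` (MCAR).

    Retained records keep their original calendar ``day_index``, so gaps
    stay visible to the lag-pairing logic.  At least one day is always
    retained (a panel cannot be empty).
    """
    if not (0.0 <= missing_prob < 1.0):
        raise ValueError("missing_prob: must be in [0, 1)")
    if missing_prob == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    keep = rng.random(len(panel.records)) >= missing_prob
    if not keep.any():
        keep[rng.integers(0, len(keep))] = True
    out = panel.copy()
    out.records = panel.records.loc[keep].reset_index(drop=True)
    return out


def write_truth_yaml(panels: list[SubjectPanel], config: SimConfig, path) -> None:
    """Sidecar ground truth: cohort parameters plus per-subject styles/seeds."""
    doc = {
        "config": asdict(config),
        "subjects": {
            p.subject_id: {
                "group": p.group,
                "phq9": p.phq9,
                "gad7": p.gad7,
                "style": p.meta.get("style"),
                "subject_seed": p.meta.get("subject_seed"),
            }
            for p in panels
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_cohort(panels: list[SubjectPanel], config: SimConfig, csv_path, truth_path=None) -> None:
    """Write the cohort CSV and, optionally, its ground-truth sidecar."""
    write_panel_csv(panels, csv_path)
    if truth_path is not None:
        write_truth_yaml(panels, config, truth_path)
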