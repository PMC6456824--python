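"""Presentation-only bar charts; all numbers live in the results JSON."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import bootstrap_mean_effect


def plot_t_sweep(sweeps: dict, path) -> None:
    """Mean personal effect per direction: unmatched and matched at each T."""
    fig, ax = plt.subplots(figsize=(7, 4))
    directions = list(sweeps)
    width = 0.8 / max(len(directions), 1)
    labels = None
    for k, d in enumerate(directions):
        summaries = sweeps[d].summaries()
        labels = ["unmatched"] + [f"T={s.T}" for s in summaries[1:]]
        xs = np.arange(len(summaries)) + k * width
        ax.bar(xs, [s.mean_effect for s in summaries], width=width,
               yerr=[s.sd_effect for s in summaries], capsize=3, label=d)
    ax.set_xticks(np.arange(len(labels)) + width * (len(directions) - 1) / 2)
    ax.set_xticklabels(labels)
    ax.set_ylabel("mean personal causal effect")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_effects(sweeps: dict, path, n_boot: int = 100, seed: int = 0) -> None:
    """Mean personal effect per symptom group, both directions, at T=1."""
    fig, ax = plt.subplots(figsize=(7, 4))
    directions = list(sweeps)
    width = 0.8 / max(len(directions), 1)
    groups = ["control", "depressed", "anxious", "depressed_anxious"]
    for k, d in enumerate(directions):
        sweep = sweeps[d]
        ref_T = 1 if 1 in sweep.matched else sorted(sweep.matched)[0]
        eff = sweep.effects[f"T{ref_T}"]
        means, sds = [], []
        for g in groups:
            try:
                s = bootstrap_mean_effect(eff, n_boot=n_boot, seed=seed, group=g)
                means.append(s.mean_effect)
                sds.append(s.sd_effect)
            except ValueError:
                means.append(np.nan)
                sds.append(0.0)
        xs = np.arange(len(groups)) + k * width
        ax.bar(xs, means, width=width, yerr=sds, capsize=3, label=d)
    ax.set_xticks(np.arange(len(groups)) + width * (len(directions) - 1) / 2)
    ax.set_xticklabels(groups, rotation=15)
    ax.set_ylabel("mean personal causal effect")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
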