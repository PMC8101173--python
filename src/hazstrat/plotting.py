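"""Diagnostic plots: residual smooths, pseudo-observation curves,
martingale residual processes, constant-effect overlays and Arjas plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .aalen_add import ConstantEffectResult, MRProcessSet
from .arjas_gof import ArjasCurves
from .pseudo_obs import EffectCurves


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_residual_smooth(x, residuals, smooth_xy, xlabel, path, ylabel="martingale residual"):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, residuals, s=6, alpha=0.4, color="grey")
    ax.plot(*smooth_xy, color="C0")
    ax.axhline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    _save(fig, path)


def plot_effect_curves(curves: EffectCurves, xlabel, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for j, t in enumerate(curves.times):
        ax.plot(curves.x, curves.curves[j], label=f"t={t:.2g}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("log(-log S)" if curves.transform == "cloglog" else "-log(S)/t")
    ax.legend(fontsize=6, ncol=3)
    _save(fig, path)


def plot_mrp(mrp: MRProcessSet, path):
    k = len(mrp.strata)
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), sharey=True, squeeze=False)
    for ax, g in zip(axes.ravel(), mrp.strata):
        ax.plot(mrp.times, mrp.observed[g], color="C0")
        ax.plot(mrp.times, mrp.lower[g], ls="--", color="C0", lw=0.8)
        ax.plot(mrp.times, mrp.upper[g], ls="--", color="C0", lw=0.8)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(str(g), fontsize=8)
        ax.set_xlabel("time")
    _save(fig, path)


def plot_constant_effect(chk: ConstantEffectResult, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(chk.times, chk.band_lower, ":", color="C0", lw=0.8)
    ax.plot(chk.times, chk.band_upper, ":", color="C0", lw=0.8)
    ax.plot(chk.times, chk.line, "--", color="C1", label=f"slope {chk.line_slope:.3g}")
    ax.set_xlabel("time")
    ax.set_ylabel(f"cumulative effect: {chk.covariate}")
    ax.legend(fontsize=8)
    _save(fig, path)


def plot_arjas(curves: ArjasCurves, path):
    k = len(curves.strata)
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), squeeze=False)
    for ax, g in zip(axes.ravel(), curves.strata):
        ax.plot(curves.expected[g], curves.observed[g], color="C0")
        lim = max(float(np.max(curves.observed[g])), float(np.max(curves.expected[g])), 1.0)
        ax.plot([0, lim], [0, lim], "--", color="k", lw=0.8)
        ax.set_title(str(g), fontsize=8)
        ax.set_xlabel("expected events")
        ax.set_ylabel("observed events")
    _save(fig, path)
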