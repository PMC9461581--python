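"""Scripted reproductions of the package's headline experiments.

Each experiment runs the full pipeline (simulate -> evaluate / fit)
at a scale controlled by ``scale_factor`` (1.0 = the reference
problem sizes below, which are already desk-scale reductions of the
original figure-quality runs) and returns tidy result tables;
``outdir`` additionally writes CSV tables and PNG figures.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    MODEL_CLASSES,
    PriorBox,
    confusion_experiment,
    map_estimate,
    relative_error,
)
from .model import GroupModel, PatchEnvironment, SimulationSettings
from .reward import evaluate_limit_case, evaluate_strategy, sweep_symmetric
from .simulate import dataset_pairs, simulate_dataset

__all__ = ["run_experiment", "EXPERIMENTS"]


def _scaled(n: int, scale: float, minimum: int = 1) -> int:
    return max(int(round(n * scale)), minimum)


def limit_comparison(scale_factor: float, seed: int, outdir: Path | None = None) -> pd.DataFrame:
    """Reward rates of the limiting strategies (NC, D_inf, P_inf) at low
    and high initial food, with the departure threshold optimized per
    case over a grid."""
    n_trials = _scaled(10_000, scale_factor, 200)
    theta_grid = np.linspace(-3.0, -0.2, 15)
    rows = []
    for rho in (2.0, 6.0):
        env = PatchEnvironment(rho=rho, tau=5.0, alpha=1.0, travel_time=5.0)
        for case in ("NC", "D_inf", "P_inf"):
            best = None
            for theta in theta_grid:
                if case == "NC":
                    model = GroupModel.symmetric("none", 2, theta, 0.0, 1.0, env)
                    rr = evaluate_strategy(
                        model, SimulationSettings(dt=0.005, t_max=300.0,
                                                  n_trials=n_trials, seed=seed)
                    ).rr
                else:
                    rr = evaluate_limit_case(case, env, theta, 1.0)[0]
                if best is None or rr > best[0]:
                    best = (rr, theta)
            rows.append({"rho": rho, "case": case, "rr": best[0],
                         "theta_opt": best[1], "n_trials": n_trials})
    df = pd.DataFrame(rows)
    if outdir is not None:
        df.to_csv(outdir / "limit_comparison.csv", index=False)
        _plot_limits(df, outdir / "limit_comparison.png")
    return df


def _sweep(mode: str, scale_factor: float, seed: int, outdir: Path | None, name: str):
    n_trials = _scaled(4000, scale_factor, 100)
    env = PatchEnvironment(rho=4.0, tau=5.0, alpha=1.0, travel_time=5.0)
    theta_grid = np.linspace(-4.0, -0.25, 10)
    kappa_grid = (
        np.linspace(0.0, 2.0, 6) if mode == "diffusive" else np.linspace(0.0, 3.0, 6)
    )
    result = sweep_symmetric(
        mode, theta_grid, kappa_grid, 1.0, env,
        SimulationSettings(dt=0.005, t_max=300.0, n_trials=n_trials, seed=seed),
    )
    df = result.to_frame()
    if outdir is not None:
        df.to_csv(outdir / f"{name}.csv", index=False)
        _plot_sweep(result, mode, outdir / f"{name}.png")
    return df


def diffusive_sweep(scale_factor: float, seed: int, outdir: Path | None = None):
    """RR heat map over (theta, kappa) for a symmetric diffusive pair."""
    return _sweep("diffusive", scale_factor, seed, outdir, "diffusive_sweep")


def pulsatile_sweep(scale_factor: float, seed: int, outdir: Path | None = None):
    """RR heat map over (theta, kappa) for a symmetric pulsatile pair."""
    return _sweep("pulsatile", scale_factor, seed, outdir, "pulsatile_sweep")


def parameter_recovery(scale_factor: float, seed: int, outdir: Path | None = None,
                  sample_sizes: tuple[int, ...] = (50, 500)) -> pd.DataFrame:
    """MAP parameter recovery: prior-drawn truths, simulated datasets,
    relative error of the recovered parameters per class and sample size."""
    n_draws = _scaled(20, scale_factor, 2)
    prior = PriorBox()
    env = PatchEnvironment(rho=2.0, tau=5.0, alpha=1.0, travel_time=5.0)
    rng = np.random.default_rng(seed)
    sim_dt = 0.005
    rows = []
    for model_class in MODEL_CLASSES:
        for draw in range(n_draws):
            truth = prior.sample(rng, model_class)
            model = GroupModel.symmetric(
                model_class, 2, truth["theta"], truth.get("kappa") or 0.0, truth["b"], env
            )
            master = simulate_dataset(
                model,
                SimulationSettings(dt=sim_dt, t_max=300.0,
                                   n_trials=max(sample_sizes),
                                   seed=int(rng.integers(2**31))),
            )
            t1_all, t2_all, tie_all = dataset_pairs(master)
            for n in sample_sizes:
                pairs = (t1_all[:n], t2_all[:n], tie_all[:n])
                fit = map_estimate(pairs, model_class, prior, env=env,
                                   data_resolution=sim_dt)
                rows.append({
                    "model_class": model_class,
                    "draw": draw,
                    "n_pairs": n,
                    "rel_err": relative_error(fit.estimate, truth, model_class),
                    **{f"true_{k}": v for k, v in truth.items() if v is not None},
                    **{f"hat_{k}": v for k, v in fit.estimate.items()},
                })
    df = pd.DataFrame(rows)
    if outdir is not None:
        df.to_csv(outdir / "parameter_recovery.csv", index=False)
        _plot_recovery(df, outdir / "parameter_recovery.png")
    return df


def model_confusion(scale_factor: float, seed: int, outdir: Path | None = None):
    """Model-identification confusion matrix at prior-drawn parameters."""
    n_draws = _scaled(30, scale_factor, 2)
    prior = PriorBox()
    env = PatchEnvironment(rho=2.0, tau=5.0, alpha=1.0, travel_time=5.0)
    cm = confusion_experiment(n_draws, n_pairs=50, prior=prior, seed=seed, env=env)
    df = cm.to_frame()
    if outdir is not None:
        df.to_csv(outdir / "model_confusion.csv")
        _plot_confusion(df, outdir / "model_confusion.png")
    return df


EXPERIMENTS = {
    "limit_comparison": limit_comparison,
    "diffusive_sweep": diffusive_sweep,
    "pulsatile_sweep": pulsatile_sweep,
    "parameter_recovery": parameter_recovery,
    "model_confusion": model_confusion,
}


def run_experiment(name: str, scale_factor: float = 1.0, seed: int = 0,
                   outdir=None) -> pd.DataFrame:
    """Run a named experiment; writes tables and figures when ``outdir``
    is given."""
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; options: {sorted(EXPERIMENTS)}"
        )
    if not scale_factor > 0:
        raise ValueError("scale_factor must be positive")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    return EXPERIMENTS[name](scale_factor, seed, outdir)


# -- plotting (matplotlib, Agg) ---------------------------------------------


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_limits(df, path):
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(7, 3), sharey=True)
    for ax, rho in zip(axes, sorted(df["rho"].unique())):
        sub = df[df["rho"] == rho]
        ax.bar(sub["case"], sub["rr"])
        ax.set_title(f"rho = {rho:g}")
        ax.set_ylabel("reward rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(result, mode, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [result.kappa_grid[0], result.kappa_grid[-1],
              result.theta_grid[0], result.theta_grid[-1]]
    im = ax.imshow(result.rr_surface, origin="lower", aspect="auto", extent=extent)
    ax.plot(result.kappa_grid, result.optimal_theta, color="grey", lw=2,
            label="optimal theta (smoothed)")
    ax.set_xlabel("coupling strength kappa")
    ax.set_ylabel("threshold theta")
    ax.set_title(f"reward rate, {mode} coupling")
    ax.legend(loc="lower right", fontsize=8)
    fig.colorbar(im, ax=ax, label="RR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_recovery(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, cls in enumerate(MODEL_CLASSES):
        for j, n in enumerate(sorted(df["n_pairs"].unique())):
            vals = df[(df["model_class"] == cls) & (df["n_pairs"] == n)]["rel_err"]
            ax.boxplot(vals, positions=[i * 3 + j], widths=0.6)
    ax.set_xticks([3 * i + 0.5 for i in range(3)])
    ax.set_xticklabels(MODEL_CLASSES)
    ax.set_ylabel("relative error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_confusion(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(df.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(3), df.columns)
    ax.set_yticks(range(3), df.index)
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{df.iloc[i, j]:.2f}", ha="center", va="center",
                    color="white")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
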