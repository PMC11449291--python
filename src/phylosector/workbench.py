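"""Configuration-driven experiment orchestration.

An experiment config is a plain dict (YAML- or JSON-serializable) fully
describing one synthetic study: the effect-vector draw, selection
parameters, phylogeny level(s), methods and a root seed.  ``run_experiment``
executes it deterministically and writes tidy CSV tables, figures and a
provenance file next to them.  Bundled configs reproduce the package's
reference experiments (ICOD spectrum vs. its block-diagonal and analytic
approximations; spectra under increasing phylogeny; the recovery-vs-mu
sweep; eigenvector components vs. earliest mutation generation).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import estimators as est
from . import evaluation as ev
from . import seqsim as sim

__all__ = ["ValidationReport", "validate_config", "run_experiment", "bundled_config", "BUNDLED"]

_KNOWN_KEYS = {
    "experiment", "L", "L_S", "sector_mean", "sector_sd", "bg_mean", "bg_sd",
    "flip_fraction", "kappa_rule", "kappa", "tau_star", "n_levels", "mu",
    "mu_grid", "tree_file", "rate_constant", "M", "n_realizations", "methods",
    "pseudocounts", "eigen_ends", "seed", "fast",
}

_DEFAULTS = dict(
    L=200, L_S=20, sector_mean=5.0, sector_sd=0.5, bg_mean=0.5, bg_sd=0.5,
    flip_fraction=0.0, kappa_rule="10/sum_D2", tau_star=90.0, n_levels=11,
    M=2048, methods=("icod", "covariance", "sca", "conservation"),
    pseudocounts={}, eigen_ends={}, seed=0, fast=False,
)

# Realization counts: full follows the reference protocol, fast is for CI.
REALIZATIONS_FULL = 100
REALIZATIONS_FAST = 10

BUNDLED = {
    # ICOD spectrum vs block-diagonal and analytic outer-product approximations
    "fig2": dict(experiment="icod_spectrum", M=14000),
    # ICOD / covariance / SCA spectra with and without selection, several mu
    "fig3": dict(experiment="spectra", mu_grid=(5, 15, 50)),
    # recovery vs mu for all methods
    "fig4": dict(experiment="sweep", mu_grid=(5, 10, 15, 25, 50, 75, 100)),
    # eigenvector components vs earliest mutation generation G
    "fig5": dict(experiment="g_components", mu_grid=(50, 5)),
    # sweep scored with the opposite end of each spectrum
    "s3": dict(
        experiment="sweep", mu_grid=(5, 10, 15, 25, 50, 75, 100),
        methods=("icod", "covariance", "sca"),
        eigen_ends={"icod": "smallest", "sca": "smallest", "covariance": "largest"},
    ),
    # per-rank recovery across the whole spectrum at three phylogeny levels
    "s4": dict(experiment="rank_recovery", mu_grid=(15, 5)),
    # sweep on an arbitrary newick tree with Poisson mutation counts
    "s7": dict(experiment="newick_sweep", rate_constant=10.0),
}


@dataclass
class ValidationReport:
    unknown_keys: list = field(default_factory=list)
    problems: list = field(default_factory=list)
    derived: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.unknown_keys and not self.problems


def bundled_config(name: str) -> dict:
    if name not in BUNDLED:
        raise KeyError(f"no bundled experiment {name!r}; have {sorted(BUNDLED)}")
    cfg = dict(_DEFAULTS)
    cfg.update(BUNDLED[name])
    return cfg


def _resolve(config: dict):
    cfg = dict(_DEFAULTS)
    cfg.update(config)
    effects = sim.make_effect_vector(
        L=cfg["L"], L_S=cfg["L_S"], sector_mean=cfg["sector_mean"],
        sector_sd=cfg["sector_sd"], bg_mean=cfg["bg_mean"], bg_sd=cfg["bg_sd"],
        flip_fraction=cfg["flip_fraction"],
        seed=np.random.SeedSequence(entropy=cfg["seed"], spawn_key=(0xD,)),
    )
    if cfg.get("kappa") is not None:
        kappa = float(cfg["kappa"])
    elif cfg["kappa_rule"] == "10/sum_D2":
        kappa = sim.kappa_for_target(effects.D, 10.0)
    else:
        raise ValueError(f"unknown kappa_rule {cfg['kappa_rule']!r}")
    params = sim.SelectionParams(kappa=kappa, tau_star=cfg["tau_star"])
    return cfg, effects, params


def validate_config(config: dict) -> ValidationReport:
    """Report-only validation: unknown keys, out-of-range values, and the
    derived quantities (resolved kappa, realization count)."""
    report = ValidationReport()
    report.unknown_keys = sorted(set(config) - _KNOWN_KEYS)
    cfg = dict(_DEFAULTS)
    cfg.update({k: v for k, v in config.items() if k in _KNOWN_KEYS})
    if cfg.get("mu") is not None and cfg["mu"] < 0:
        report.problems.append("mu must be >= 0")
    for mu in cfg.get("mu_grid") or ():
        if mu < 0:
            report.problems.append(f"mu_grid contains negative value {mu}")
    if not 0 <= cfg["L_S"] <= cfg["L"]:
        report.problems.append("need 0 <= L_S <= L")
    if cfg.get("experiment") == "newick_sweep" and not cfg.get("tree_file"):
        report.problems.append("newick experiment requires tree_file")
    if cfg.get("tree_file") and not Path(cfg["tree_file"]).exists():
        report.problems.append(f"tree file not found: {cfg['tree_file']}")
    try:
        _, effects, params = _resolve(cfg)
        report.derived["kappa"] = params.kappa
        report.derived["kappa_sum_D2"] = params.kappa * float(np.sum(effects.D**2))
        report.derived["null_recovery"] = ev.null_recovery(effects)
    except (ValueError, KeyError) as err:
        report.problems.append(str(err))
    report.derived["n_realizations"] = (
        cfg.get("n_realizations") or (REALIZATIONS_FAST if cfg.get("fast") else REALIZATIONS_FULL)
    )
    return report


# ---------------------------------------------------------------------------
# experiment bodies
# ---------------------------------------------------------------------------


def _spectrum_frame(matrices: dict) -> pd.DataFrame:
    frames = []
    for label, mat in matrices.items():
        t = ev.spectrum_table(mat)
        t.insert(0, "dataset", label)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _plot_spectra(table: pd.DataFrame, path: Path, logy: bool = False) -> None:
    fig, axes = plt.subplots(1, table["panel"].nunique(), figsize=(4 * table["panel"].nunique(), 3.2), squeeze=False)
    for ax, (panel, sub) in zip(axes.ravel(), table.groupby("panel", sort=False)):
        for label, grp in sub.groupby("dataset", sort=False):
            ax.plot(grp["rank"], grp["eigenvalue"], ".", ms=3, label=label)
        ax.set_title(panel)
        ax.set_xlabel("rank")
        ax.set_ylabel("eigenvalue")
        if logy:
            ax.set_yscale("log")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _run_icod_spectrum(cfg, effects, params, outdir, n_real):
    msa = sim.sample_equilibrium_msa(cfg["M"], effects, params, seed=_seed(cfg, 1))
    icod = est.icod_two_state(msa)
    block = ev.block_diagonal_approximation(icod, effects.sector_indices)
    analytic = params.kappa * np.outer(effects.D, effects.D)
    np.fill_diagonal(analytic, 0.0)
    table = _spectrum_frame({"icod": icod, "block-diagonal": block, "analytic": analytic})
    table["panel"] = "ICOD spectrum"
    table.to_csv(outdir / "spectra.csv", index=False)
    _plot_spectra(table, outdir / "spectra.png")
    return {"M": cfg["M"], "top_eigenvalue": float(ev.spectrum_table(icod)["eigenvalue"][0])}


def _run_spectra(cfg, effects, params, outdir, n_real):
    datasets = {}
    eq = sim.sample_equilibrium_msa(cfg["M"], effects, params, seed=_seed(cfg, 1))
    datasets["no phylogeny"] = eq
    for k, mu in enumerate(cfg["mu_grid"]):
        rec = sim.evolve_on_binary_tree(None, mu=mu, n=cfg["n_levels"], effects=effects,
                                        params=params, seed=_seed(cfg, 10 + k))
        datasets[f"mu={mu}"] = rec.leaf_msa
        neut = sim.evolve_on_binary_tree(None, mu=mu, n=cfg["n_levels"], effects=effects,
                                         params=params, neutral=True, seed=_seed(cfg, 100 + k))
        datasets[f"mu={mu} (neutral)"] = neut.leaf_msa
    frames = []
    for panel, builder in (
        ("ICOD", lambda m: est.icod_two_state(m)),
        ("covariance", lambda m: est.covariance_two_state(m)),
        ("SCA", lambda m: est.sca_matrix(m, q=2)),
    ):
        t = _spectrum_frame({lbl: builder(m) for lbl, m in datasets.items()})
        t["panel"] = panel
        frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "spectra.csv", index=False)
    _plot_spectra(table, outdir / "spectra.png")
    return {"datasets": list(datasets)}


def _run_sweep(cfg, effects, params, outdir, n_real):
    table = ev.phylogeny_sweep(
        mu_values=cfg["mu_grid"], methods=tuple(cfg["methods"]),
        n_realizations=n_real, effects=effects, params=params,
        n_levels=cfg["n_levels"], pseudocounts=cfg["pseudocounts"],
        eigen_ends=cfg["eigen_ends"], seed=_seed(cfg, 1),
    )
    table.to_csv(outdir / "sweep.csv", index=False)
    summary = ev.summarize_sweep(table)
    summary.to_csv(outdir / "sweep_summary.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method, grp in summary.groupby("method"):
        ax.errorbar(grp["mu"], grp["recovery"], yerr=grp["recovery_sd"], label=method, marker="o")
    ax.axhline(ev.null_recovery(effects), ls="--", c="k", label="null")
    ax.set_xlabel(r"mutations per branch $\mu$")
    ax.set_ylabel("recovery")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "recovery_vs_mu.png", dpi=150)
    plt.close(fig)
    return {"n_realizations": n_real, "methods": list(cfg["methods"])}


def _run_g_components(cfg, effects, params, outdir, n_real):
    frames = []
    for mu in cfg["mu_grid"]:
        for real in range(n_real):
            rec = sim.evolve_on_binary_tree(None, mu=mu, n=cfg["n_levels"], effects=effects,
                                            params=params, seed=_seed(cfg, 1000 * mu + real))
            vectors = {m: ev.score_msa(rec.leaf_msa, m) for m in ("icod", "covariance", "sca")}
            t = ev.g_component_table(rec, vectors)
            t["mu"] = mu
            t["realization"] = real
            t["sector"] = effects.sector_mask[t["site"].to_numpy()]
            frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "g_components.csv", index=False)
    fig, axes = plt.subplots(len(cfg["mu_grid"]), 3, figsize=(11, 3 * len(cfg["mu_grid"])), squeeze=False)
    for r, mu in enumerate(cfg["mu_grid"]):
        for c, method in enumerate(("icod", "covariance", "sca")):
            sub = table[(table["mu"] == mu) & (table["method"] == method)]
            groups = [g["component"].to_numpy() for _, g in sub.groupby("G")]
            axes[r, c].violinplot(groups, positions=sorted(sub["G"].unique()), widths=0.8)
            axes[r, c].set_title(f"{method}, mu={mu}")
            axes[r, c].set_xlabel("earliest mutation generation G")
            axes[r, c].set_ylabel("|component|")
    fig.tight_layout()
    fig.savefig(outdir / "components_vs_G.png", dpi=150)
    plt.close(fig)
    return {"mu_grid": list(cfg["mu_grid"]), "n_realizations": n_real}


def _run_rank_recovery(cfg, effects, params, outdir, n_real):
    datasets = {"no phylogeny": sim.sample_equilibrium_msa(cfg["M"], effects, params, seed=_seed(cfg, 1))}
    for k, mu in enumerate(cfg["mu_grid"]):
        rec = sim.evolve_on_binary_tree(None, mu=mu, n=cfg["n_levels"], effects=effects,
                                        params=params, seed=_seed(cfg, 10 + k))
        datasets[f"mu={mu}"] = rec.leaf_msa
    rows = []
    for label, msa in datasets.items():
        for method, builder in (
            ("icod", lambda m: est.icod_two_state(m)),
            ("covariance", lambda m: est.covariance_two_state(m)),
            ("sca", lambda m: est.sca_matrix(m, q=2)),
        ):
            mat = builder(msa).values
            vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
            for rank in range(vals.size):
                v = vecs[:, vals.size - 1 - rank]
                rows.append((label, method, rank, ev.recovery(v, effects)))
    table = pd.DataFrame(rows, columns=["dataset", "method", "rank", "recovery"])
    table.to_csv(outdir / "rank_recovery.csv", index=False)
    return {"datasets": list(datasets)}


def _run_newick_sweep(cfg, effects, params, outdir, n_real):
    tree_text = Path(cfg["tree_file"]).read_text()
    rows = []
    for real in range(n_real):
        rec = sim.evolve_on_newick_tree(None, tree_text, cfg["rate_constant"], effects,
                                        params, seed=_seed(cfg, real))
        for method in cfg["methods"]:
            vec = ev.score_msa(rec.leaf_msa, method)
            rows.append((method, rec.mean_mutations_per_lineage, real,
                         ev.recovery(vec, effects),
                         ev.symmetrized_auc(vec, effects.sector_mask)))
    table = pd.DataFrame(rows, columns=["method", "mean_mutations", "realization", "recovery", "sym_auc"])
    table.to_csv(outdir / "newick_sweep.csv", index=False)
    return {"rate_constant": cfg["rate_constant"], "n_realizations": n_real}


_BODIES = {
    "icod_spectrum": _run_icod_spectrum,
    "spectra": _run_spectra,
    "sweep": _run_sweep,
    "g_components": _run_g_components,
    "rank_recovery": _run_rank_recovery,
    "newick_sweep": _run_newick_sweep,
}


def _seed(cfg: dict, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=cfg["seed"], spawn_key=(stream,))


def run_experiment(config: dict, outdir, n_realizations: Optional[int] = None) -> dict:
    """Run one configured experiment; write tables, figures and provenance
    into ``outdir``.  Deterministic given the config's root seed."""
    report = validate_config(config)
    if not report.ok:
        raise ValueError(
            "invalid config: " + "; ".join(
                [f"unknown key {k!r}" for k in report.unknown_keys] + report.problems
            )
        )
    cfg, effects, params = _resolve(config)
    body = _BODIES.get(cfg.get("experiment"))
    if body is None:
        raise ValueError(f"unknown experiment {cfg.get('experiment')!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_real = n_realizations or cfg.get("n_realizations") or (
        REALIZATIONS_FAST if cfg.get("fast") else REALIZATIONS_FULL
    )
    t0 = time.perf_counter()
    info = body(cfg, effects, params, outdir, n_real)
    elapsed = time.perf_counter() - t0
    from . import __version__

    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "resolved_kappa": params.kappa,
        "package_version": __version__,
        "elapsed_seconds": elapsed,
        **info,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return provenance
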