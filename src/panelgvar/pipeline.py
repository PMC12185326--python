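"""End-to-end orchestration: simulate -> preprocess -> fit -> stabilize ->
derive -> compare -> communities, with a machine-readable summary and a run
manifest.

Every stochastic stage draws its seed deterministically from the global
seed and the stage name (SeedSequence over the global seed plus a stable
hash of the name), so a manifest fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .community import community_cooccurrence
from .compare import align_common_nodes, permute_and_compare
from .model import PanelGVAR
from .simulate import generate_population, smd_like_config
from .stability import bootstrap_edges

__all__ = ["RunConfig", "run_pipeline", "fit_from_moments", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global_seed, crc(stage))."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "panelgvar_run"
    panel_path: str | None = None        # read panel instead of simulating
    moments_path: str | None = None      # skip straight to the fit
    seed: int = 0
    # simulation stage (used when no panel/moments input is given)
    sim_n_individuals: int = 2000
    sim_p: int = 8
    sim_binarize: bool = True
    # stage toggles
    do_bootstrap: bool = True
    do_compare: bool = False
    do_communities: bool = True
    # stage parameters
    bootstrap_iterations: int = 250
    bootstrap_holdout: float = 0.25
    compare_iterations: int = 250
    compare_group_column: str | None = None
    community_runs: int = 1000
    community_spins: int = 8
    prune_alpha: float = 0.01
    recovery_n: int | None = None
    fdr_level: float = 0.05
    covariate_names: list | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and write all artifacts.

    Returns the summary dictionary that is also written to summary.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    manifest = {
        "config": config.as_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.as_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
        "python": platform.python_version(),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "bootstrap", "compare", "communities")
        },
    }
    _write_json(manifest, out / "manifest.json")

    # ---- input acquisition ------------------------------------------------
    if config.moments_path is not None:
        moments = io.read_moments(config.moments_path)
        panel = None
    elif config.panel_path is not None:
        panel = io.read_panel(config.panel_path)
        moments = None
    else:
        sim = smd_like_config(
            n_individuals=config.sim_n_individuals,
            p=config.sim_p,
            binarize=config.sim_binarize,
            seed=stage_seed(config.seed, "simulate"),
        )
        panel = generate_population(sim)
        io.write_panel(panel, out / "panel.csv")
        moments = None

    # ---- fit --------------------------------------------------------------
    if moments is None:
        model = PanelGVAR.from_panel(
            panel, covariate_names=config.covariate_names
        )
        io.write_moments(model.moments, out / "moments.txt")
    else:
        model = PanelGVAR(moments)
    results = model.fit()
    io.write_model_json(results, out / "model.json")
    summary["fit_indices"] = results.fit_indices.as_dict()
    summary["converged"] = results.converged

    net = results.to_networks()
    io.write_edge_list(net.edge_list("temporal"), out / "edges_temporal.tsv")
    io.write_edge_list(
        net.edge_list("contemporaneous"), out / "edges_contemporaneous.tsv"
    )
    io.write_edge_list(net.edge_list("between"), out / "edges_between.tsv")
    io.write_centrality(results.centrality(), out / "centrality.tsv")
    cent = results.centrality()
    summary["centrality"] = {
        "c_in": dict(zip(cent.node_labels, cent.c_in)),
        "c_out": dict(zip(cent.node_labels, cent.c_out)),
    }

    comparison = results.prune(alpha=config.prune_alpha)
    summary["prune"] = {
        "delta_chi2": comparison.delta_chi2,
        "delta_df": comparison.delta_df,
        "p_value": comparison.p_value,
    }
    recovery = results.simulate_recovery(
        n=config.recovery_n, seed=stage_seed(config.seed, "recovery")
    )
    summary["recovery"] = {
        "edge_correlation": recovery.edge_correlation,
        "rmsea": recovery.fit_indices.rmsea,
        "cfi": recovery.fit_indices.cfi,
        "tli": recovery.fit_indices.tli,
    }

    # ---- bootstrap stability ----------------------------------------------
    if config.do_bootstrap and panel is not None:
        boot = bootstrap_edges(
            panel,
            iterations=config.bootstrap_iterations,
            holdout=config.bootstrap_holdout,
            seed=stage_seed(config.seed, "bootstrap"),
            covariate_names=config.covariate_names,
        )
        labels = boot.node_labels
        with open(out / "bootstrap_edges.tsv", "w") as fh:
            fh.write("source\ttarget\tmean\tlower\tupper\tstabilized\tmatrix\n")
            for mat_name in ("temporal", "contemporaneous", "between"):
                est = getattr(boot, mat_name)
                for i, ti in enumerate(labels):
                    for j, tj in enumerate(labels):
                        if mat_name != "temporal" and j >= i:
                            continue
                        fh.write(
                            f"{tj}\t{ti}\t{est.mean[i, j]:.6g}\t"
                            f"{est.lower[i, j]:.6g}\t{est.upper[i, j]:.6g}\t"
                            f"{est.stabilized[i, j]:.6g}\t{mat_name}\n"
                        )
        summary["bootstrap"] = {
            "n_iterations": boot.n_iterations,
            "n_dropped": boot.n_dropped,
            "temporal_nonzero_stabilized": int(
                np.count_nonzero(boot.temporal.stabilized)
            ),
        }
        community_input = boot.temporal.stabilized
        community_labels = labels
    else:
        community_input = net.temporal
        community_labels = net.node_labels

    # ---- group comparison -------------------------------------------------
    if config.do_compare and panel is not None and config.compare_group_column:
        col = config.compare_group_column
        groups = {
            str(g): panel.subset(
                panel.df.loc[panel.df[col] == g, "id"].unique()
            )
            for g in sorted(panel.df[col].unique())
        }
        aligned = align_common_nodes(
            groups, covariate_names=config.covariate_names
        )
        comp = permute_and_compare(
            aligned,
            iterations=config.compare_iterations,
            seed=stage_seed(config.seed, "compare"),
            level=config.fdr_level,
            covariate_names=config.covariate_names,
        )
        frac = {
            f"{a}-{b}|{mat}": v
            for ((a, b), mat), v in comp.summary_fractions().items()
        }
        summary["comparison"] = {
            "fraction_significant": frac,
            "n_iterations": comp.n_iterations,
        }
        for (pair, mat), ec in comp.comparisons.items():
            name = f"compare_{pair[0]}_{pair[1]}_{mat}.tsv"
            with open(out / name, "w") as fh:
                fh.write("source\ttarget\tobserved_diff\tp\tq\tsignificant\n")
                labels = comp.node_labels
                for i in range(len(labels)):
                    for j in range(len(labels)):
                        if mat != "temporal" and j >= i:
                            continue
                        fh.write(
                            f"{labels[j]}\t{labels[i]}\t"
                            f"{ec.observed_diff[i, j]:.6g}\t"
                            f"{ec.p_values[i, j]:.6g}\t"
                            f"{ec.q_values[i, j]:.6g}\t"
                            f"{int(ec.significant[i, j])}\n"
                        )

    # ---- communities ------------------------------------------------------
    if config.do_communities:
        com = community_cooccurrence(
            community_input,
            runs=config.community_runs,
            spins=config.community_spins,
            seed=stage_seed(config.seed, "communities"),
            node_labels=community_labels,
        )
        np.savetxt(
            out / "cooccurrence.tsv", com.cooccurrence, delimiter="\t",
            header="\t".join(com.node_labels), comments="",
        )
        _write_json(
            [{"nodes": list(nodes), "percent": pct}
             for nodes, pct in com.top_communities],
            out / "top_communities.json",
        )
        summary["communities"] = {
            "top": [
                {"nodes": list(nodes), "percent": pct}
                for nodes, pct in com.top_communities
            ],
            "n_runs": com.n_runs,
        }

    _write_json(summary, out / "summary.json")
    return summary


def fit_from_moments(moments_path, order: str | None = None):
    """Fit + derive networks from a stacked-moments file only.

    This is the path for re-estimating networks from published covariance
    matrices: no panel, no bootstrap.
    Returns (results, networks).
    """
    moments = io.read_moments(moments_path, order=order)
    results = PanelGVAR(moments).fit()
    return results, results.to_networks()
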