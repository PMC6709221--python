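"""Model/Results interfaces for the heartbeat-induced-network analysis.

`HeartbeatNetworkModel` is built from per-subject induced and baseline
connectivity matrices; `fit()` runs the network-based statistic and returns a
`HeartbeatNetworkResults` carrying the t matrix, component FWE p-values, the
HIS network, and graph-analysis methods. `MoodAffectModel` relates the affect
mood component to module synchronization candidates via stepwise regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import affect as _affect
from . import graph as _graph
from . import nbs as _nbs

__all__ = ["HeartbeatNetworkModel", "HeartbeatNetworkResults", "MoodAffectModel", "MoodAffectResults"]


class HeartbeatNetworkModel:
    """Group-level inference of the heartbeat-induced network.

    Parameters
    ----------
    induced, baseline
        Per-subject region x region connectivity matrices (lists of arrays or
        `WindowedMatrix`), one pair per subject, on the same region set.
    region_labels
        Optional region names for reporting.
    """

    def __init__(self, induced, baseline, region_labels=None):
        self.induced = [m.matrix if hasattr(m, "matrix") else np.asarray(m, float) for m in induced]
        self.baseline = [m.matrix if hasattr(m, "matrix") else np.asarray(m, float) for m in baseline]
        if len(self.induced) != len(self.baseline):
            raise ValueError("induced and baseline lists must be the same length")
        self.n_subjects = len(self.induced)
        self.n_regions = self.induced[0].shape[0]
        self.region_labels = list(region_labels) if region_labels is not None else [
            f"region_{i}" for i in range(self.n_regions)
        ]

    @classmethod
    def from_stacks(cls, stacks, baseline_window=(-300.0, -100.0),
                    induced_window=(200.0, 600.0), region_labels=None):
        """Build from per-subject `ConnectivityStack`s by window averaging."""
        from .spectral import window_average

        induced = [window_average(s, induced_window) for s in stacks]
        baseline = [window_average(s, baseline_window) for s in stacks]
        return cls(induced, baseline, region_labels=region_labels)

    def fit(self, t_threshold=2.51, n_permutations=5000, alpha=0.05, seed=None):
        config = _nbs.NBSConfig(
            t_threshold=t_threshold, n_permutations=n_permutations, alpha=alpha, seed=seed
        )
        result = _nbs.nbs(self.induced, self.baseline, config)
        his = _nbs.build_his(result, self.induced, self.baseline, region_labels=self.region_labels)
        return HeartbeatNetworkResults(self, result, his)


class HeartbeatNetworkResults:
    """NBS inference results plus graph-level characterization."""

    def __init__(self, model: HeartbeatNetworkModel, nbs_result, his):
        self.model = model
        self.nbs_result = nbs_result
        self.his = his

    # -- inference ---------------------------------------------------------
    @property
    def t_matrix(self):
        return self.nbs_result.t_matrix

    @property
    def fwe_pvalues(self):
        return self.nbs_result.fwe_p

    @property
    def density(self):
        return self.his.density

    @property
    def edges(self):
        return self.his.edges

    # -- graph analysis ----------------------------------------------------
    def hubs(self, partition=None, top=None) -> pd.DataFrame:
        """Node metrics table sorted by strength (region, strength, BC, ...)."""
        table = _graph.node_metrics(
            self.his.weights, partition=partition, region_labels=self.model.region_labels
        )
        table = table.sort_values("strength", ascending=False).reset_index(drop=True)
        return table.head(top) if top else table

    def consensus_modules(self, n_runs=10000, tau=0.2, seed=None, gamma=1.0):
        return _graph.consensus_partition(
            self.his.weights, n_runs=n_runs, tau=tau, seed=seed, gamma=gamma
        )

    def modularity_significance(self, n_random=100, seed=None, n_runs=100, tau=0.2):
        return _graph.modularity_significance(
            self.his.weights, n_random=n_random, seed=seed, n_runs=n_runs, tau=tau
        )

    def module_synchronization(self, partition):
        return _graph.module_sync(self.his.weights, partition)

    def between_modules(self, partition):
        return _graph.between_module_graph(self.his.weights, partition)

    def node_roles(self, partition):
        return _graph.z_p_roles(self.his.weights, partition)

    def subject_edge_sync(self, edges=None) -> np.ndarray:
        """Per-subject summed (induced - baseline) over HIN edges."""
        edges = edges if edges is not None else self.his.edges
        out = np.zeros(self.model.n_subjects)
        for s, (ind, base) in enumerate(zip(self.model.induced, self.model.baseline)):
            out[s] = sum(ind[i, j] - base[i, j] for i, j in edges)
        return out

    def plot_timecourse(self, stack, ax=None, baseline_window=(-300.0, -100.0)):
        """Diagnostic plot of the HIN synchronization time course."""
        import matplotlib.pyplot as plt

        tc = _graph.sync_timecourse(stack, self.his.edges, baseline_window=baseline_window)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(stack.time_points, tc)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("time relative to R-peak (ms)")
        ax.set_ylabel("summed wPLI-D (baseline-subtracted)")
        return ax

    def summary(self) -> str:
        lines = [
            "Heartbeat-induced network (NBS) results",
            "=" * 46,
            f"subjects:            {self.model.n_subjects}",
            f"regions:             {self.model.n_regions}",
            f"t threshold:         {self.nbs_result.config.t_threshold}",
            f"permutations:        {self.nbs_result.null_distribution.size}"
            + (" (exhaustive)" if self.nbs_result.exhaustive else ""),
            f"components found:    {len(self.nbs_result.components)}",
        ]
        for k, (c, p) in enumerate(zip(self.nbs_result.components, self.nbs_result.fwe_p)):
            lines.append(
                f"  component {k}: {len(c.edges)} edges, stat={c.stat:.2f}, FWE p={p:.4g}"
            )
        lines += [
            f"HIN edges:           {len(self.his.edges)}",
            f"HIN density:         {self.his.density:.4f}",
        ]
        return "\n".join(lines)


class MoodAffectModel:
    """Mood (first affect PC) vs module-synchronization candidates."""

    def __init__(self, affect_table: pd.DataFrame, sync_candidates: pd.DataFrame):
        self.affect_table = affect_table
        self.sync_candidates = sync_candidates
        if len(affect_table) != len(sync_candidates):
            raise ValueError("affect table and candidates must have one row per subject")

    def fit(self, enter=0.05, remove=0.10) -> "MoodAffectResults":
        pc = _affect.first_pc(self.affect_table)
        step = _affect.stepwise_regression(
            pc.scores, self.sync_candidates, enter=enter, remove=remove
        )
        robust = {}
        for name in step.selected:
            robust[name] = _affect.robust_checks(
                pc.scores, self.sync_candidates[name].to_numpy()
            )
        return MoodAffectResults(pc, step, robust)


class MoodAffectResults:
    def __init__(self, pc, stepwise, robust):
        self.pc = pc
        self.stepwise = stepwise
        self.robust = robust

    @property
    def variance_explained(self):
        return self.pc.variance_explained

    @property
    def selected(self):
        return self.stepwise.selected

    @property
    def rsquared(self):
        return self.stepwise.rsquared

    def summary(self) -> str:
        lines = [
            "Mood vs module synchronization",
            "=" * 46,
            f"PC1 variance explained: {self.pc.variance_explained:.3f}",
            "PC1 loadings:",
        ]
        for name, val in self.pc.loadings.items():
            lines.append(f"  {name:<18s} {val:+.3f}")
        if self.stepwise.intercept_only:
            lines.append("stepwise model: intercept only (no predictor entered)")
        else:
            lines.append(
                f"stepwise model: F({self.stepwise.df_model},{self.stepwise.df_resid})="
                f"{self.stepwise.fvalue:.2f}, p={self.stepwise.f_pvalue:.4g}, "
                f"R^2={self.stepwise.rsquared:.3f}"
            )
            for name in self.stepwise.selected:
                lines.append(
                    f"  {name}: beta={self.stepwise.params[name]:+.3f}, "
                    f"p={self.stepwise.pvalues[name]:.4g}"
                )
                rc = self.robust[name]
                lines.append(
                    f"    robust slope p={rc.robust_p:.4g}, "
                    f"Spearman rho={rc.spearman_rho:+.3f} (p={rc.spearman_p:.4g})"
                )
        return "\n".join(lines)
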