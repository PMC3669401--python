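"""Statsmodels-style model/results objects wrapping the functional layer.

``Panda`` holds the aligned evidence (the raw seed triple); ``fit()`` runs
the message-passing loop and returns a ``PandaResults`` carrying the refined
networks, the convergence diagnostics and convenience accessors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PandaConfig, PandaState, normalize_seeds, run_panda
from .evaluate import EvalReport, evaluate_network
from .netio import (
    ExpressionMatrix,
    LabeledBipartiteNetwork,
    LabeledSymmetricNetwork,
    SeedNetworks,
    build_seed_networks,
    read_expression,
    read_pairwise_table,
    write_network,
)
from .postprocess import EdgeSet, top_k_edges

__all__ = ["Panda", "PandaResults"]


class Panda:
    """Message-passing refinement model over a TF->gene prior, TF-TF
    interactions and gene expression.

    Parameters
    ----------
    seeds : SeedNetworks
        Raw (un-normalized) seed triple; build with
        :func:`pandanet.build_seed_networks`, :meth:`Panda.from_files` or
        :meth:`Panda.from_dataframes`.

    Examples
    --------
    >>> model = Panda.from_files("prior.tsv", "ppi.tsv", "expression.tsv")
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(self, seeds: SeedNetworks):
        self.seeds = seeds

    @classmethod
    def from_files(
        cls,
        prior_path,
        ppi_path=None,
        expression_path=None,
        universe: str = "intersection",
    ) -> "Panda":
        """Build the model from delimited text tables (see ``netio``)."""
        prior = read_pairwise_table(prior_path, kind="prior")
        ppi = read_pairwise_table(ppi_path, kind="ppi") if ppi_path else None
        expr = read_expression(expression_path) if expression_path else None
        return cls(build_seed_networks(prior, ppi, expr, universe=universe))

    @classmethod
    def from_dataframes(
        cls,
        prior: pd.DataFrame,
        ppi: pd.DataFrame | None = None,
        expression: pd.DataFrame | None = None,
        universe: str = "intersection",
    ) -> "Panda":
        """Build from in-memory tables.

        ``prior`` and ``ppi`` are edge tables whose first two (or three)
        columns are source, target[, weight]; ``expression`` is gene x sample
        with genes on the index.
        """

        def _records(df, kind):
            recs = {}
            for row in df.itertuples(index=False):
                s, t = str(row[0]), str(row[1])
                w = float(row[2]) if len(row) > 2 else 1.0
                recs[(s, t)] = max(recs.get((s, t), -np.inf), w)
                if kind == "ppi" and s != t:
                    recs[(t, s)] = max(recs.get((t, s), -np.inf), w)
            return [(s, t, w) for (s, t), w in recs.items()]

        expr = None
        if expression is not None:
            expr = ExpressionMatrix(
                gene_labels=[str(g) for g in expression.index],
                sample_labels=[str(c) for c in expression.columns],
                values=expression.to_numpy(dtype=float),
            )
        return cls(
            build_seed_networks(
                _records(prior, "prior"),
                _records(ppi, "ppi") if ppi is not None else None,
                expr,
                universe=universe,
            )
        )

    def fit(
        self,
        alpha: float = 0.05,
        tol: float = 1e-5,
        max_iter: int = 500,
        use_ppi: bool = True,
        use_expression: bool = True,
    ) -> "PandaResults":
        """Run the message-passing loop to convergence."""
        config = PandaConfig(
            alpha=alpha,
            tol=tol,
            max_iter=max_iter,
            use_ppi=use_ppi,
            use_expression=use_expression,
        )
        state, trace = run_panda(self.seeds, config)
        return PandaResults(self, config, state, trace)


class PandaResults:
    """Refined networks plus convergence diagnostics.

    Attributes
    ----------
    regulatory, cooperativity, coregulation : labeled networks in z-score
        edge-weight units.
    converged : whether the inter-iteration distance fell below tol.
    n_iter : iterations performed.
    distance_trace : per-iteration mean absolute change of W.
    """

    def __init__(self, model: Panda, config: PandaConfig, state: PandaState, trace):
        self.model = model
        self.config = config
        self._state = state
        self.distance_trace = list(trace)
        seeds = model.seeds
        self.regulatory = LabeledBipartiteNetwork(
            seeds.tf_labels, seeds.gene_labels, state.W
        )
        self.cooperativity = LabeledSymmetricNetwork(seeds.tf_labels, state.P)
        self.coregulation = LabeledSymmetricNetwork(seeds.gene_labels, state.C)

    @property
    def converged(self) -> bool:
        return self._state.converged

    @property
    def n_iter(self) -> int:
        return self._state.t

    @property
    def final_distance(self) -> float:
        return self._state.last_distance

    def top_edges(self, k: int = 1000, condition: str = "") -> EdgeSet:
        """The k strongest refined regulatory edges."""
        return top_k_edges(self.regulatory, k, condition=condition)

    def evaluate(self, gold, prior=None, specificity: float = 0.9) -> EvalReport:
        """Score the refined regulatory network against a gold standard."""
        return evaluate_network(self.regulatory, gold, prior=prior, specificity=specificity)

    def save(self, out_dir, format: str = "edge-list") -> None:
        """Write the three refined networks under ``out_dir``."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        ext = "tsv" if format == "matrix" else "txt"
        write_network(self.regulatory, f"{out_dir}/regulatory.{ext}", format=format)
        write_network(self.cooperativity, f"{out_dir}/cooperativity.{ext}", format=format)
        write_network(self.coregulation, f"{out_dir}/coregulation.{ext}", format=format)

    def plot_convergence(self, ax=None):
        """Distance trace on a log scale (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(range(1, len(self.distance_trace) + 1), self.distance_trace)
        ax.axhline(self.config.tol, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean |ΔW|")
        return ax

    def summary(self) -> str:
        """Human-readable fit summary."""
        seeds = self.model.seeds
        W = self.regulatory.weights
        lines = [
            "Message-passing network refinement",
            "==================================",
            f"TFs:                {len(seeds.tf_labels)}",
            f"genes:              {len(seeds.gene_labels)}",
            f"alpha:              {self.config.alpha}",
            f"tolerance:          {self.config.tol:g}",
            f"iterations:         {self.n_iter} (max {self.config.max_iter})",
            f"converged:          {self.converged}",
            f"final distance:     {self.final_distance:.3e}",
            f"W weight range:     [{W.min():.3f}, {W.max():.3f}]",
            f"degenerate entries: {self._state.degenerate_entries}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<PandaResults: {len(self.regulatory.tf_labels)} TFs x "
            f"{len(self.regulatory.gene_labels)} genes, "
            f"{'converged' if self.converged else 'not converged'} "
            f"in {self.n_iter} iterations>"
        )
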