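"""Robustness of centrality-based node rankings to unknown interactions.

Drug databases record only the interactions discovered so far; absent edges
may be undiscovered rather than nonexistent.  The simulation injects a
fraction q of the non-edge universe as "unknown" edges, recomputes a
centrality, and quantifies (a) ranking stability as the Kendall tau
correlation between the node rankings before and after injection and (b)
distribution-shape stability as the change in the fitted power-law exponent
alpha.  The procedure is repeated R times per q (default R = 100) to report
means and variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .build import InteractionNetwork, nonedge_universe
from .netstats import CentralityTable, compute_centrality
from .powerlaw import DegenerateSampleError, fit_power_law, loglog_slope

logger = logging.getLogger(__name__)

DEFAULT_BETWEENNESS_NODE_BOUND = 2000


@dataclass
class RobustnessConfig:
    centrality_name: str = "degree"
    q_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1)
    R: int = 100
    seed: int = 0
    alpha_mode: str = "mle"          # or "loglog"
    tau_variant: str = "b"           # tie-corrected; "a" = untied normalisation
    q_mode: str = "nonedge"          # m = round(q * |E_t \ E|); "edges": m = round(q * |E|)
    alpha_xmin_mode: str = "refit"   # or "fixed": reuse the reference xmin
    betweenness_node_bound: int = DEFAULT_BETWEENNESS_NODE_BOUND

    def __post_init__(self) -> None:
        if self.centrality_name not in ("degree", "betweenness"):
            raise ValueError("centrality must be 'degree' or 'betweenness'")
        if not self.q_grid or not all(0 < q < 1 for q in self.q_grid):
            raise ValueError("q values must lie in (0, 1)")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.tau_variant not in ("a", "b"):
            raise ValueError("tau_variant must be 'a' or 'b'")
        if self.alpha_mode not in ("mle", "loglog"):
            raise ValueError("alpha_mode must be 'mle' or 'loglog'")
        if self.q_mode not in ("nonedge", "edges"):
            raise ValueError("q_mode must be 'nonedge' or 'edges'")


@dataclass
class QPoint:
    q: float
    n_injected_edges: int
    tau_mean: float | None
    tau_var: float | None
    tau_min: float | None
    tau_max: float | None
    alpha_mean: float | None
    alpha_var: float | None
    n_tau_degenerate: int
    n_alpha_failed: int
    taus: list[float] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)


@dataclass
class RobustnessCurve:
    centrality_name: str
    reference_alpha: float | None
    points: list[QPoint]

    def tau_means(self) -> list[float | None]:
        return [p.tau_mean for p in self.points]


def inject_unknown_edges(
    net: InteractionNetwork,
    q: float,
    rng: np.random.Generator,
    *,
    q_mode: str = "nonedge",
) -> InteractionNetwork:
    """Return G' = G plus m uniformly sampled absent edges; G is untouched.

    m = round(q * |E_t \\ E|) in the default mode (E_t = all structurally
    permitted pairs on the current node set), or round(q * |E|) in "edges"
    mode.  Injection respects bipartiteness: for a DTI network only
    drug→target pairs are eligible.  m = 0 after rounding returns G unchanged;
    m larger than the universe is capped with a warning.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    universe = nonedge_universe(net)
    base = universe.size if q_mode == "nonedge" else net.n_edges
    m = int(round(q * base))
    if m == 0:
        logger.info("q=%g rounds to zero injected edges; returning G unchanged", q)
        return net
    if m > universe.size:
        logger.warning(
            "requested %d injected edges but only %d non-edges exist; capping",
            m, universe.size,
        )
        m = universe.size
        if m == 0:
            return net
    return net.with_edges(universe.sample(m, rng))


def _tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-a: (concordant - discordant) / (n(n-1)/2)."""
    n = x.size
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    s = float(np.sum(np.triu(dx * dy, k=1)))
    return s / (n * (n - 1) / 2)


def ranking_tau(
    c1: CentralityTable, c2: CentralityTable, variant: str = "b"
) -> float | None:
    """Kendall tau between two centrality tables aligned by node.

    Default tau-b corrects for ties; tau-b is undefined when either vector is
    constant, in which case None is returned (a degenerate comparison is
    reported absent, never coerced to 0).  tau-a uses the untied n(n-1)/2
    normalisation and is always defined for n >= 2.
    """
    if set(c1.values) != set(c2.values):
        raise ValueError("centrality tables cover different node sets")
    nodes = sorted(c1.values)
    x = c1.aligned(nodes)
    y = c2.aligned(nodes)
    if variant == "a":
        return _tau_a(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    tau = sps.kendalltau(x, y, variant="b").statistic
    if not np.isfinite(tau):
        return None
    return float(tau)


def _alpha_of(table: CentralityTable, mode: str, xmin: float | None) -> float | None:
    vals = table.positive_values()
    try:
        if mode == "loglog":
            return -loglog_slope(vals)
        fit = fit_power_law(vals, xmin=xmin)
        return fit.alpha
    except (ValueError, DegenerateSampleError):
        return None


def run_robustness(net: InteractionNetwork, config: RobustnessConfig) -> RobustnessCurve:
    """Run the injection simulation over the q grid, R replicates each.

    Replicates use independent spawned random substreams keyed on the root
    seed, so identical (network, config) inputs give identical curves.  A
    replicate whose tau is degenerate (constant ranking) is excluded from the
    mean and counted; the same holds for failed alpha fits.
    """
    if (
        config.centrality_name == "betweenness"
        and net.n_nodes > config.betweenness_node_bound
    ):
        raise ValueError(
            f"betweenness robustness limited to networks with <= "
            f"{config.betweenness_node_bound} nodes (got {net.n_nodes})"
        )
    reference = compute_centrality(net, config.centrality_name)
    ref_xmin: float | None = None
    ref_alpha = _alpha_of(reference, config.alpha_mode, None)
    if config.alpha_xmin_mode == "fixed" and ref_alpha is not None and config.alpha_mode == "mle":
        ref_xmin = fit_power_law(reference.positive_values()).xmin

    points: list[QPoint] = []
    for qi, q in enumerate(config.q_grid):
        # stable per-(seed, q-index, replicate) substreams
        substreams = np.random.SeedSequence([config.seed, qi]).spawn(config.R)
        taus: list[float] = []
        alphas: list[float] = []
        n_degen = 0
        n_alpha_failed = 0
        m_injected = 0
        for rep in range(config.R):
            rng = np.random.default_rng(substreams[rep])
            perturbed = inject_unknown_edges(net, q, rng, q_mode=config.q_mode)
            m_injected = perturbed.n_edges - net.n_edges
            table = compute_centrality(perturbed, config.centrality_name)
            tau = ranking_tau(reference, table, variant=config.tau_variant)
            if tau is None:
                n_degen += 1
            else:
                taus.append(tau)
            alpha = _alpha_of(table, config.alpha_mode, ref_xmin)
            if alpha is None:
                n_alpha_failed += 1
            else:
                alphas.append(alpha)
        points.append(
            QPoint(
                q=q,
                n_injected_edges=m_injected,
                tau_mean=float(np.mean(taus)) if taus else None,
                tau_var=float(np.var(taus)) if taus else None,
                tau_min=float(np.min(taus)) if taus else None,
                tau_max=float(np.max(taus)) if taus else None,
                alpha_mean=float(np.mean(alphas)) if alphas else None,
                alpha_var=float(np.var(alphas)) if alphas else None,
                n_tau_degenerate=n_degen,
                n_alpha_failed=n_alpha_failed,
                taus=taus,
                alphas=alphas,
            )
        )
    return RobustnessCurve(
        centrality_name=config.centrality_name,
        reference_alpha=ref_alpha,
        points=points,
    )
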