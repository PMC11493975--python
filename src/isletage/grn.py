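"""Consensus gene-regulatory-network filtering and regulon analysis.

Stochastic network-inference runs (gradient-boosting co-expression module
detection) produce different TF->target edge lists each time.  The consensus
filter retains only edges reproduced in at least a fraction ``min_support``
of runs (default 80%) and averages each edge's importance over the runs in
which it appears.  Downstream utilities binarize per-cell regulon activity,
find modules of co-active TFs by correlation clustering, and rank TF
influence by betweenness centrality on the consensus graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

Edge = tuple[str, str, float]  # (tf, target, importance)


@dataclass
class RunSet:
    """Edge lists from repeated stochastic inference runs."""

    runs: list[list[Edge]]

    def __post_init__(self):
        for i, run in enumerate(self.runs):
            pairs = [(tf, tgt) for tf, tgt, _ in run]
            if len(pairs) != len(set(pairs)):
                raise ValueError(f"run {i} contains duplicate (tf, target) pairs")
            for tf, tgt, imp in run:
                if imp < 0:
                    raise ValueError(f"negative importance {imp} for {tf}->{tgt}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class ConsensusNetwork:
    """Support-filtered consensus graph.

    edges is a DataFrame (tf, target, support, mean_importance); support is
    the exact fraction of runs containing the edge, computed in integer
    arithmetic before division.
    """

    edges: pd.DataFrame
    min_support: float
    n_runs: int

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.tf,
                row.target,
                support=row.support,
                mean_importance=row.mean_importance,
            )
        return g


def consensus_filter(
    runs: RunSet, min_support: float = 0.80, absent_as_zero: bool = False
) -> ConsensusNetwork:
    """Retain edges appearing in at least ``min_support`` of runs (inclusive).

    Support is appearances/n_runs as an exact rational; the retention test
    compares integer counts (count * denominator >= numerator-style), so an
    edge in exactly 80 of 100 runs is retained at min_support = 0.80 with no
    floating drift.  mean_importance averages over the runs containing the
    edge; with ``absent_as_zero`` it averages over all runs instead (absent
    runs contributing zero).
    """
    if runs.n_runs < 1:
        raise ValueError("empty run set")
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    counts: dict[tuple[str, str], int] = {}
    sums: dict[tuple[str, str], float] = {}
    for run in runs.runs:
        for tf, tgt, imp in run:
            counts[(tf, tgt)] = counts.get((tf, tgt), 0) + 1
            sums[(tf, tgt)] = sums.get((tf, tgt), 0.0) + imp
    thr = Fraction(min_support).limit_denominator(10**9)
    rows = []
    for (tf, tgt), c in sorted(counts.items()):
        if Fraction(c, runs.n_runs) >= thr:
            denom = runs.n_runs if absent_as_zero else c
            rows.append((tf, tgt, c / runs.n_runs, sums[(tf, tgt)] / denom))
    return ConsensusNetwork(
        edges=pd.DataFrame(
            rows, columns=["tf", "target", "support", "mean_importance"]
        ),
        min_support=min_support,
        n_runs=runs.n_runs,
    )


# ---------------------------------------------------------------------------
# Regulon activity binarization
# ---------------------------------------------------------------------------


def _logit(p):
    return np.log(p / (1.0 - p))


def _binarize_column(values: np.ndarray, rng_seed: int = 0):
    """Threshold one regulon column via a two-component Gaussian mixture on
    logit-activities; returns (threshold, on_mask, bimodal_flag).

    Values clipped at the [0, 1] boundary are excluded from the mixture fit
    (the logit would inflate them into a spurious mode); they are still
    classified by the resulting threshold.  If the two-component fit is not
    favored by BIC over one component, or one component carries < 5% of the
    mass, the column is treated as unimodal and conservatively called
    all-OFF.
    """
    eps = 1e-4
    interior = (values > eps) & (values < 1.0 - eps)
    if interior.sum() < 10:
        return np.inf, np.zeros(len(values), dtype=bool), False
    x = _logit(values[interior]).reshape(-1, 1)
    if np.ptp(x) == 0:
        return np.inf, np.zeros(len(values), dtype=bool), False
    gm2 = GaussianMixture(n_components=2, random_state=rng_seed, n_init=3).fit(x)
    gm1 = GaussianMixture(n_components=1, random_state=rng_seed).fit(x)
    # demand well-separated modes (Ashman's D >= 3) besides a BIC win and
    # >= 5% mass per component: a skewed unimodal column otherwise splits
    # into two overlapping components
    mu = gm2.means_.ravel()
    sd = np.sqrt(gm2.covariances_.ravel())
    ashman_d = np.sqrt(2.0) * abs(mu[0] - mu[1]) / np.sqrt(sd[0] ** 2 + sd[1] ** 2)
    if gm2.bic(x) >= gm1.bic(x) or gm2.weights_.min() < 0.05 or ashman_d < 3.0:
        return np.inf, np.zeros(len(values), dtype=bool), False
    means = gm2.means_.ravel()
    lo, hi = np.sort(means)
    # crossing point of posteriors between the two means
    grid = np.linspace(lo, hi, 512).reshape(-1, 1)
    post = gm2.predict_proba(grid)
    hi_comp = int(np.argmax(means))
    cross = np.argmax(post[:, hi_comp] >= 0.5)
    thr_logit = float(grid[cross, 0])
    thr = 1.0 / (1.0 + np.exp(-thr_logit))
    return thr, values >= thr, True


def binarize_activity(activity: pd.DataFrame, seed: int = 0):
    """Binarize a cells x regulons activity matrix to ON/OFF per regulon.

    Per column, a two-component Gaussian mixture on logit-transformed
    activities gives the ON/OFF threshold (posterior crossing point between
    the component means); columns that are not bimodal by BIC fall back to
    all-OFF.  Returns ``(binary, thresholds)``: a boolean DataFrame and a
    Series of per-regulon thresholds (inf for all-OFF columns).
    """
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    vals = activity.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("activity matrix contains non-finite values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("activities must lie in [0, 1]")
    binary = {}
    thresholds = {}
    for col in activity.columns:
        thr, on, _ = _binarize_column(activity[col].to_numpy(), rng_seed=seed)
        binary[col] = on
        thresholds[col] = thr
    return (
        pd.DataFrame(binary, index=activity.index),
        pd.Series(thresholds, name="threshold"),
    )


# ---------------------------------------------------------------------------
# TF co-activity modules
# ---------------------------------------------------------------------------


def tf_correlation_modules(
    activity: pd.DataFrame,
    n_modules: int | None = None,
    height: float | None = None,
    method: str = "average",
):
    """Pearson co-activity matrix of regulons plus hierarchical modules.

    Correlation is computed across cells for every regulon pair;
    zero-variance columns are excluded with a warning.  Average-linkage
    clustering on distance 1 - r yields module labels, cut either into
    ``n_modules`` clusters or at distance ``height``.

    Returns ``(corr, modules)``: the correlation DataFrame and a Series
    mapping regulon -> module id.
    """
    import warnings as _warnings

    if activity.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    variances = activity.var(axis=0)
    usable = activity.loc[:, variances > 0]
    dropped = [c for c in activity.columns if c not in usable.columns]
    if dropped:
        _warnings.warn(f"excluding zero-variance regulons: {dropped}", stacklevel=2)
    if usable.shape[1] < 2:
        raise ValueError("fewer than 2 usable (non-constant) regulon columns")
    corr = usable.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    if n_modules is not None:
        labels = fcluster(Z, t=n_modules, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = fcluster(Z, t=0.5, criterion="distance")
    modules = pd.Series(labels, index=corr.index, name="module")
    return corr, modules


# ---------------------------------------------------------------------------
# Influence ranking
# ---------------------------------------------------------------------------


def betweenness(
    net: ConsensusNetwork | nx.DiGraph, normalized: bool = False, weighted: bool = False
) -> pd.Series:
    """Betweenness centrality of nodes on the directed consensus graph.

    Unweighted shortest paths by default (an importance-weighted variant
    uses 1/mean_importance as edge length).  Node size in influence plots
    is proportional to this score.
    """
    g = net.to_graph() if isinstance(net, ConsensusNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weight = None
    if weighted:
        for u, v, d in g.edges(data=True):
            d["_len"] = 1.0 / max(d.get("mean_importance", 1.0), 1e-12)
        weight = "_len"
    scores = nx.betweenness_centrality(g, normalized=normalized, weight=weight)
    return pd.Series(scores, name="betweenness").sort_index()


# ---------------------------------------------------------------------------
# Run-set IO (one TSV per run: tf, target, importance)
# ---------------------------------------------------------------------------


def write_runs_tsv(runs: RunSet, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, run in enumerate(runs.runs):
        pd.DataFrame(run, columns=["tf", "target", "importance"]).to_csv(
            d / f"run_{i:03d}.tsv", sep="\t", index=False
        )


def read_runs_tsv(directory) -> RunSet:
    from pathlib import Path

    paths = sorted(Path(directory).glob("run_*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no run_*.tsv files in {directory}")
    runs = []
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        runs.append(list(df[["tf", "target", "importance"]].itertuples(index=False, name=None)))
    return RunSet(runs=runs)
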