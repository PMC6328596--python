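"""Cross-kingdom co-occurrence networks from rarefied counts.

Pairwise Pearson correlations among the best-sequenced taxa (computed on
counts rarefied to a common depth, so sequencing effort cannot drive
co-occurrence) are thresholded at a two-sided significance level to form
an undirected graph whose nodes carry kingdom labels and whose edges keep
the correlation sign.  Degree and (unweighted, unnormalized) betweenness
centrality identify influential taxa; an OLS of degree on kingdom tests
whether one kingdom is systematically better connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountTable
from .diversity import ResampledTable, rarefy
from .filters import top_taxa

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "MicrobiomeNetwork", "correlation_matrix",
           "build_network", "centrality", "kingdom_degree_test",
           "depth_sensitivity"]


@dataclass
class CorrelationMatrix:
    taxa: list[str]
    kingdom: pd.Series            # taxon -> kingdom
    r: pd.DataFrame               # symmetric Pearson coefficients
    p: pd.DataFrame               # two-sided p from the t transform
    n_samples: int
    undefined: list[str] = field(default_factory=list)  # zero-variance taxa

    def mean_correlation(self) -> pd.Series:
        """Per-taxon mean of its off-diagonal correlation row."""
        r = self.r.to_numpy().copy()
        np.fill_diagonal(r, np.nan)
        return pd.Series(np.nanmean(r, axis=1), index=self.taxa)


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson coefficient via the t transform
    with n - 2 degrees of freedom."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def correlation_matrix(
    resampled: ResampledTable,
    kingdom: pd.Series,
    taxa: list[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson r and p among taxa of a rarefied table.

    Zero-variance taxa have undefined correlations; they are recorded and
    their rows/columns set to NaN (and later excluded from the graph).
    """
    counts = resampled.counts if taxa is None else resampled.counts[taxa]
    taxa = list(counts.columns)
    X = counts.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = X.std(axis=0)
    undefined = [t for t, s in zip(taxa, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    p = pearson_p(r, n)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    p[bad, :] = np.nan
    p[:, bad] = np.nan
    return CorrelationMatrix(
        taxa=taxa,
        kingdom=kingdom.reindex(taxa),
        r=pd.DataFrame(r, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n_samples=n,
        undefined=undefined,
    )


@dataclass
class MicrobiomeNetwork:
    graph: nx.Graph
    edge_alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(c: CorrelationMatrix, edge_alpha: float = 0.01) -> MicrobiomeNetwork:
    """Graph with an edge wherever the correlation p-value < ``edge_alpha``.

    Taxa with undefined correlations become isolated nodes.
    """
    g = nx.Graph()
    for t in c.taxa:
        g.add_node(t, kingdom=c.kingdom[t])
    p = c.p.to_numpy()
    r = c.r.to_numpy()
    for i in range(len(c.taxa)):
        for j in range(i + 1, len(c.taxa)):
            if np.isfinite(p[i, j]) and p[i, j] < edge_alpha:
                g.add_edge(c.taxa[i], c.taxa[j], r=float(r[i, j]),
                           sign=1 if r[i, j] > 0 else -1)
    return MicrobiomeNetwork(graph=g, edge_alpha=edge_alpha)


def centrality(net: MicrobiomeNetwork) -> pd.DataFrame:
    """Degree and unnormalized shortest-path betweenness per node."""
    g = net.graph
    degree = dict(g.degree())
    between = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame({
        "kingdom": pd.Series(nx.get_node_attributes(g, "kingdom")),
        "degree": pd.Series(degree),
        "betweenness": pd.Series(between),
    })


def kingdom_degree_test(net: MicrobiomeNetwork) -> tuple[float, float]:
    """OLS of node degree on a fungi indicator.

    Returns (slope, two-sided p).  The slope equals the difference in mean
    degree (fungi minus bacteria).
    """
    cent = centrality(net)
    kingdoms = cent["kingdom"].unique()
    if len(kingdoms) < 2:
        raise ValueError("kingdom_degree_test needs both kingdoms in the network")
    x = (cent["kingdom"] == "fungi").to_numpy(dtype=float)
    y = cent["degree"].to_numpy(dtype=float)
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def depth_sensitivity(
    table: CountTable,
    kingdom: pd.Series,
    depths: list[int],
    seed: int = 0,
    reference_depth: int = 400,
    top_n: int | None = None,
    edge_alpha: float = 0.01,
) -> pd.DataFrame:
    """Stability of node degree across rarefaction depths.

    For each depth the table is rarefied, the network rebuilt, and the
    Spearman rank correlation of node degree against the reference-depth
    network reported, together with sample retention.
    """
    if len(depths) < 2 and reference_depth not in depths:
        raise ValueError("need at least two depths")
    all_depths = sorted(set(depths) | {reference_depth})
    rng = np.random.default_rng(seed)
    n_samples = table.n_samples
    degrees: dict[int, pd.Series] = {}
    retention: dict[int, int] = {}
    for depth in all_depths:
        sub = rarefy(table, depth, rng=rng)
        retention[depth] = len(sub.kept_samples)
        if len(sub.kept_samples) < 0.5 * n_samples:
            logger.warning("depth %d retains only %d/%d samples",
                           depth, len(sub.kept_samples), n_samples)
        use = sub
        if top_n is not None:
            ranked = top_taxa(
                CountTable(sub.counts, kingdom.reindex(sub.counts.columns),
                           pd.Series("", index=sub.counts.columns, dtype=object)),
                top_n,
            )
            use = ResampledTable(ranked.counts, depth, sub.excluded_samples,
                                 sub.seed)
        net = build_network(correlation_matrix(use, kingdom), edge_alpha)
        degrees[depth] = centrality(net)["degree"]
    ref = degrees[reference_depth]
    rows = []
    for depth in all_depths:
        shared = ref.index.intersection(degrees[depth].index)
        rho = stats.spearmanr(ref[shared], degrees[depth][shared]).statistic
        rows.append({"depth": depth, "n_samples": retention[depth],
                     "degree_rank_corr": float(rho)})
    return pd.DataFrame(rows)
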