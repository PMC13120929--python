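"""Trajectory graphs, Markov clustering and per-cluster demographics.

Significance-filtered, direction-selected event pairs are chained into a
directed graph whose edges carry the exposed-with-outcome patient count,
the same count as a percentage of the cohort, and the mean relative
risk.  The graph is partitioned with the Markov Clustering algorithm
(MCL): the symmetrized, self-looped, column-stochastic adjacency matrix
is alternately expanded (matrix power) and inflated (entrywise power
plus renormalization) until it reaches a doubly-idempotent fixed point,
whose attractor rows spell out the clusters.

For each cluster the member patients (those contributing to any
intra-cluster edge) are summarized: age at their first in-cluster
event, patient count, and the female proportion compared against the
whole cohort with a finite-population-corrected one-sample Z-test.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

from .cohort_io import Cohort, Sex, age_at
from .pairstats import EventIndex, PairResult, TimeRange

__all__ = [
    "TrajectoryGraph",
    "MclParams",
    "ClusterReport",
    "build_graph",
    "mcl_cluster",
    "test_gender_proportion",
    "cluster_statistics",
    "export_graph",
    "two_event_cluster_table",
]


@dataclass(frozen=True)
class MclParams:
    expansion: int = 2
    inflation: float = 2.0
    max_iter: int = 200
    convergence_tol: float = 1e-8
    edge_weight: str = "n_patients"  # "unit" | "rr" | "n_patients"
    prune_below: float = 1e-12

    def __post_init__(self) -> None:
        if self.expansion < 2 or self.inflation <= 1:
            raise ValueError("need expansion >= 2 and inflation > 1")


@dataclass
class TrajectoryGraph:
    """Directed event graph with annotated edges.

    ``graph`` is a :class:`networkx.DiGraph`; each edge carries
    ``n_patients``, ``pct`` (of the cohort), ``rr`` and ``patients``
    (the exposed-with-outcome patient ids behind the count).
    """

    graph: nx.DiGraph
    window: TimeRange
    min_patients: int
    cohort_size: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, dict]]:
        return [(a, b, d) for a, b, d in self.graph.edges(data=True)]


@dataclass
class ClusterReport:
    cluster_id: str
    events: set[str]
    n_patients: int
    pct_of_cohort: float
    mean_age: float
    sd_age: float
    n_female: int
    pct_female: float
    z_p_value: float


def build_graph(
    pairs: Sequence[PairResult],
    min_patients: int,
    cohort_size: int,
    window: TimeRange | None = None,
) -> TrajectoryGraph:
    """Chain surviving pairs into a directed graph.

    ``pairs`` must already be significance-filtered and
    direction-selected; edges below ``min_patients`` patients are
    dropped, and nodes exist only as endpoints of surviving edges.
    """
    g = nx.DiGraph()
    win = window
    for r in pairs:
        win = win or r.window
        if r.n_patients < min_patients:
            continue
        g.add_edge(
            r.event_a,
            r.event_b,
            n_patients=r.n_patients,
            pct=100.0 * r.n_patients / cohort_size if cohort_size else 0.0,
            rr=r.rr_mean,
            patients=r.patients,
        )
    return TrajectoryGraph(
        graph=g,
        window=win or TimeRange(0, 365),
        min_patients=min_patients,
        cohort_size=cohort_size,
    )


# ---------------------------------------------------------------------------
# Markov clustering


def _mcl_matrix(tg: TrajectoryGraph, params: MclParams) -> tuple[list[str], np.ndarray]:
    nodes = sorted(tg.graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    m = np.zeros((len(nodes), len(nodes)))
    for a, b, d in tg.graph.edges(data=True):
        if params.edge_weight == "unit":
            w = 1.0
        elif params.edge_weight == "rr":
            w = d["rr"] if math.isfinite(d["rr"]) else 1.0
        else:
            w = float(d["n_patients"])
        i, j = pos[a], pos[b]
        # flow simulation is direction-agnostic: symmetrize by max
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    # self-loops at each node's strongest incident weight: damps the
    # period-2 oscillation of bipartite-ish components without which a
    # two-node cluster would disintegrate into singletons
    loops = np.maximum(m.max(axis=0), 1.0)
    np.fill_diagonal(m, np.maximum(m.diagonal(), loops))
    return nodes, m


def mcl_cluster(
    tg: TrajectoryGraph, params: MclParams | None = None
) -> list[set[str]]:
    """Partition the graph nodes with the Markov Clustering algorithm.

    Returns clusters as sets of node labels; every node belongs to
    exactly one cluster, and clusters never span disconnected
    components.  Raises on non-convergence.
    """
    params = params or MclParams()
    if tg.graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes, m = _mcl_matrix(tg, params)
    m = m / m.sum(axis=0, keepdims=True)
    for iteration in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < params.convergence_tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge within {params.max_iter} iterations "
            f"(residual {np.abs(m - prev).max():.3g})"
        )

    thr = 1e-6
    attractors = [i for i in range(len(nodes)) if m[i, i] > thr]
    raw = [set(np.flatnonzero(m[i] > thr).tolist()) | {i} for i in attractors]
    # merge overlapping attractor systems
    merged: list[set[int]] = []
    for c in raw:
        hits = [k for k, mc in enumerate(merged) if mc & c]
        for k in reversed(hits):
            c |= merged.pop(k)
        merged.append(c)
    assigned = set().union(*merged) if merged else set()
    for j in range(len(nodes)):
        if j not in assigned:
            target = int(np.argmax(m[:, j]))
            for c in merged:
                if target in c:
                    c.add(j)
                    break
            else:
                merged.append({j})
    return [{nodes[i] for i in c} for c in merged]


# ---------------------------------------------------------------------------
# Cluster demographics


def test_gender_proportion(
    n_female: int, n: int, ref_proportion: float, population_size: int
) -> float:
    """Two-sided one-sample proportion Z-test with finite-population correction.

    The cohort is a finite population of size N from which the cluster's
    n patients are an (assumed simple random) sample, so the binomial
    variance carries the correction factor (N-n)/(N-1):

        z = (p̂ - p0) / sqrt(p0 (1-p0) / n * (N-n)/(N-1))

    As N -> inf this reduces to the classical one-sample Z-test.
    """
    if not (0 <= n_female <= n <= population_size):
        raise ValueError("need 0 <= n_female <= n <= population_size")
    if not (0 < ref_proportion < 1):
        raise ValueError("reference proportion must be in (0, 1)")
    if n == 0:
        return math.nan
    phat = n_female / n
    if n == population_size:
        warnings.warn("cluster spans the whole cohort; FPC variance is zero")
        return 1.0 if phat == ref_proportion else 0.0
    fpc = (population_size - n) / (population_size - 1)
    se = math.sqrt(ref_proportion * (1 - ref_proportion) / n * fpc)
    z = (phat - ref_proportion) / se
    return 2.0 * norm.sf(abs(z))


def cluster_statistics(
    cluster: set[str],
    tg: TrajectoryGraph,
    cohort: Cohort,
    index: EventIndex,
    cluster_id: str = "c1",
    ref_female_proportion: float | None = None,
) -> ClusterReport:
    """Demographics of the patients behind a cluster's edges.

    A patient belongs to the cluster if they contribute to the
    exposed-with-outcome count of any edge with both endpoints inside
    the cluster.  Age is taken at the patient's first event on any
    in-cluster node.
    """
    members: set[str] = set()
    for a, b, d in tg.graph.edges(data=True):
        if a in cluster and b in cluster:
            members |= set(d["patients"])
    by_id = cohort.by_id()
    n = len(members)
    n_pop = len(cohort)
    if ref_female_proportion is None:
        n_f_pop = sum(1 for p in cohort if p.sex is Sex.FEMALE)
        ref_female_proportion = n_f_pop / n_pop if n_pop else 0.5
    if n == 0:
        return ClusterReport(
            cluster_id, set(cluster), 0, 0.0, math.nan, math.nan, 0, math.nan, math.nan
        )

    ages = []
    for pid in members:
        rec = by_id[pid]
        pos = index.position(pid)
        firsts = [
            int(index.dates[lab][pos][0])
            for lab in cluster
            if pos in index.dates.get(lab, {})
        ]
        if firsts:
            ages.append(age_at(rec, dt.date.fromordinal(min(firsts))))
    n_female = sum(1 for pid in members if by_id[pid].sex is Sex.FEMALE)
    mean_age = float(np.mean(ages)) if ages else math.nan
    sd_age = float(np.std(ages, ddof=1)) if len(ages) > 1 else math.nan
    return ClusterReport(
        cluster_id=cluster_id,
        events=set(cluster),
        n_patients=n,
        pct_of_cohort=100.0 * n / n_pop if n_pop else math.nan,
        mean_age=mean_age,
        sd_age=sd_age,
        n_female=n_female,
        pct_female=100.0 * n_female / n,
        z_p_value=test_gender_proportion(n_female, n, ref_female_proportion, n_pop),
    )


# ---------------------------------------------------------------------------
# Presentation


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def export_graph(
    tg: TrajectoryGraph,
    clusters: Sequence[set[str]],
    display_min_rr: float,
    path: Path | str,
) -> Path:
    """Write the clustered trajectory graph as a Graphviz DOT file.

    Only clusters with >= 3 events are drawn (one DOT subgraph each,
    intra-cluster edges only); edges with RR below ``display_min_rr``
    are omitted.  Edge labels read "n (pct%) RR=x"; machine-readable
    ``n``/``pct``/``rr`` attributes accompany them.  Two-event clusters
    belong in a side table (:func:`two_event_cluster_table`).
    """
    lines = ["digraph trajectories {"]
    for k, cluster in enumerate(clusters):
        if len(cluster) < 3:
            continue
        lines.append(f"  subgraph cluster_{k} {{")
        lines.append(f'    label="c{k}";')
        for node in sorted(cluster):
            lines.append(f"    {_dot_quote(node)};")
        for a, b, d in tg.graph.edges(data=True):
            if a in cluster and b in cluster and d["rr"] >= display_min_rr:
                label = f"{d['n_patients']} ({d['pct']:.2f}%) RR={d['rr']:.2f}"
                lines.append(
                    f"    {_dot_quote(a)} -> {_dot_quote(b)} "
                    f'[label="{label}", n={d["n_patients"]}, '
                    f'pct="{d["pct"]:.2f}", rr="{d["rr"]:.4g}"];'
                )
        lines.append("  }")
    lines.append("}")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def two_event_cluster_table(
    tg: TrajectoryGraph,
    clusters: Sequence[set[str]],
    display_min_rr: float = 0.0,
) -> "pd.DataFrame":
    """Two-event clusters as a table (pair, n, pct, RR), sorted by RR."""
    import pandas as pd

    rows = []
    for cluster in clusters:
        if len(cluster) != 2:
            continue
        for a, b, d in tg.graph.edges(data=True):
            if a in cluster and b in cluster and d["rr"] >= display_min_rr:
                rows.append(
                    {
                        "event_a": a,
                        "event_b": b,
                        "n_patients": d["n_patients"],
                        "pct_of_cohort": round(d["pct"], 2),
                        "rr": d["rr"],
                    }
                )
    df = pd.DataFrame(
        rows, columns=["event_a", "event_b", "n_patients", "pct_of_cohort", "rr"]
    )
    return df.sort_values("rr", ascending=False).reset_index(drop=True)
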