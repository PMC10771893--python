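"""Domain-vs-whole-protein divergence geometry.

Each unordered species pair becomes a point (x, y): x is percent identity
over the whole protein, y over the functional domain only. The plane has two
landmarks — the conservation point (100, 100), where both measures are fully
conserved, and the slope-1 diagonal y = x, on which the domain and the rest
of the protein diverge in balance. Points below the diagonal mean the domain
changes faster than the whole protein (accelerated adaptation); points above
mean the domain is the conserved part. A pair's conservation distance is the
Euclidean distance to (100, 100); group-pair clusters are summarized by the
mean and SEM of those distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from .identity import identity_matrix
from .records import ALIGNMENT_COLUMN, Msa, Region

DOMAIN_CONSERVED = "domain_conserved"
BALANCED = "balanced"
DOMAIN_ACCELERATED = "domain_accelerated"

#: exact-tie guard only; the diagonal is a strict demarcation
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class DivergencePoint:
    pair: frozenset  # two species ids
    group_pair: tuple[str, str]  # sorted group labels
    x: float  # whole-protein % identity
    y: float  # domain % identity

    def __post_init__(self):
        if not (0 <= self.x <= 100 and 0 <= self.y <= 100):
            raise ValueError("identities must be percentages in [0, 100]")

    @property
    def group_label(self) -> str:
        return ":".join(self.group_pair)


@dataclass
class ClusterSummary:
    name: str
    group_pairs: set[tuple[str, str]]
    n: int
    mean_distance: float
    sem: float | None  # absent (None) when n == 1
    balance_tally: dict[str, int]  # class -> count, sums to n


def conservation_distance(point: DivergencePoint | tuple[float, float]) -> float:
    """Euclidean distance from the (100, 100) conservation point.

    Full precision is returned; reports round to 2 decimals. Bounded in
    [0, 100 * sqrt(2)].
    """
    x, y = (point.x, point.y) if isinstance(point, DivergencePoint) else point
    return math.hypot(100.0 - x, 100.0 - y)


def classify_balance(
    point: DivergencePoint | tuple[float, float],
    tol: float = DEFAULT_TOL,
) -> str:
    """Position relative to the slope-1 diagonal: above (y > x) means the
    domain is conserved relative to the whole protein, below means it is
    accelerated, within ``tol`` of the line is balanced."""
    x, y = (point.x, point.y) if isinstance(point, DivergencePoint) else point
    if y - x > tol:
        return DOMAIN_CONSERVED
    if y - x < -tol:
        return DOMAIN_ACCELERATED
    return BALANCED


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


def cluster_summaries(
    points: list[DivergencePoint],
    partition: dict[str, set] | None = None,
    tol: float = DEFAULT_TOL,
) -> list[ClusterSummary]:
    """Aggregate points into group-pair clusters, sorted by ascending mean
    conservation distance.

    ``partition`` maps a cluster name to the set of group pairs it covers
    (each group pair may be given as a tuple or an "A:B" string); the default
    is one cluster per distinct group pair. Merged clusters — several group
    pairs whose points overlap in the plane — are configuration, not an
    automatic discovery. SEM uses the n-1 sample SD over sqrt(n) and is
    absent for single-point clusters.
    """
    observed = {p.group_pair for p in points}
    if partition is None:
        partition = {":".join(gp): {gp} for gp in sorted(observed)}
    else:
        partition = {
            name: {
                _norm_pair(*gp.split(":")) if isinstance(gp, str) else _norm_pair(*gp)
                for gp in pairs
            }
            for name, pairs in partition.items()
        }
    assignment: dict[tuple[str, str], str] = {}
    for name, pairs in partition.items():
        for gp in pairs:
            if gp in assignment:
                raise ValueError(f"group pair {gp} assigned to multiple clusters")
            assignment[gp] = name

    members: dict[str, list[DivergencePoint]] = {name: [] for name in partition}
    for p in points:
        if p.group_pair not in assignment:
            raise ValueError(f"group pair {p.group_label} not covered by the partition")
        members[assignment[p.group_pair]].append(p)

    summaries = []
    for name, pts in members.items():
        if not pts:
            continue
        dists = [conservation_distance(p) for p in pts]
        n = len(dists)
        mean = sum(dists) / n
        if n > 1:
            var = sum((d - mean) ** 2 for d in dists) / (n - 1)
            sem = math.sqrt(var) / math.sqrt(n)
        else:
            sem = None
        tally = {DOMAIN_CONSERVED: 0, BALANCED: 0, DOMAIN_ACCELERATED: 0}
        for p in pts:
            tally[classify_balance(p, tol)] += 1
        summaries.append(
            ClusterSummary(
                name=name,
                group_pairs=partition[name],
                n=n,
                mean_distance=mean,
                sem=sem,
                balance_tally=tally,
            )
        )
    summaries.sort(key=lambda s: s.mean_distance)
    return summaries


@dataclass
class DivergenceAnalysis:
    points: list[DivergencePoint]
    clusters: list[ClusterSummary]
    classes: dict[frozenset, str]  # pair -> balance class

    def point_table(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            a, b = sorted(p.pair)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "group_pair": p.group_label,
                    "whole_identity": round(p.x, 1),
                    "domain_identity": round(p.y, 1),
                    "distance": round(conservation_distance(p), 2),
                    "class": self.classes[p.pair],
                }
            )
        return pd.DataFrame(rows)

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for rank, c in enumerate(self.clusters, start=1):
            rows.append(
                {
                    "cluster": rank,
                    "name": c.name,
                    "n_pairs": c.n,
                    "mean_distance": round(c.mean_distance, 2),
                    "sem": round(c.sem, 2) if c.sem is not None else "",
                    "above_diagonal": c.balance_tally[DOMAIN_CONSERVED],
                    "on_diagonal": c.balance_tally[BALANCED],
                    "below_diagonal": c.balance_tally[DOMAIN_ACCELERATED],
                }
            )
        return pd.DataFrame(rows)


def divergence_analysis(
    msa: Msa,
    domain: Region,
    groups: dict[str, str],
    cluster_partition: dict[str, set] | None = None,
    tol: float = DEFAULT_TOL,
) -> DivergenceAnalysis:
    """One point per unordered species pair: x from the whole alignment,
    y from the domain columns; plus cluster summaries and per-point balance
    classes. Distances are computed from unrounded identities."""
    if domain.space != ALIGNMENT_COLUMN:
        raise ValueError("domain must be in alignment-column space")
    missing = set(msa.ids) - set(groups)
    if missing:
        raise ValueError(f"species without a group: {sorted(missing)}")
    whole = identity_matrix(msa)
    dom = identity_matrix(msa, domain)
    points = []
    for a, b in itertools.combinations(msa.ids, 2):
        points.append(
            DivergencePoint(
                pair=frozenset((a, b)),
                group_pair=_norm_pair(groups[a], groups[b]),
                x=whole.get(a, b),
                y=dom.get(a, b),
            )
        )
    clusters = cluster_summaries(points, cluster_partition, tol)
    classes = {p.pair: classify_balance(p, tol) for p in points}
    return DivergenceAnalysis(points=points, clusters=clusters, classes=classes)


def plot_divergence(
    analysis: DivergenceAnalysis,
    path,
    group_colors: dict[str, str] | None = None,
) -> None:
    """Scatter of (whole, domain) identity per pair with the slope-1
    diagonal; a facsimile of the conservation-geometry figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    labels_seen = set()
    for p in analysis.points:
        label = p.group_label
        color = (group_colors or {}).get(label)
        ax.scatter(
            p.x,
            p.y,
            c=color,
            label=label if label not in labels_seen else None,
            alpha=0.8,
        )
        labels_seen.add(label)
    lo = min([p.x for p in analysis.points] + [p.y for p in analysis.points] + [100])
    lo = max(0.0, lo - 5)
    ax.plot([lo, 100], [lo, 100], "k--", lw=1, label="balanced evolution (y = x)")
    ax.scatter([100], [100], marker="+", c="k", s=80)
    ax.set_xlabel("whole-protein identity (%)")
    ax.set_ylabel("domain identity (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
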