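"""Physical pre-miRNA cluster detection and class comparisons.

Pre-miRNAs on the same scaffold and strand are chained into clusters when
the intergenic gap to the chain so far is below a distance threshold
(default 5 kb); cluster density is members per kb of span.  Chaining uses
the running maximum end of the open chain, which makes the result exactly
the connected components of the pairwise gap-below-threshold relation even
for nested or overlapping intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import PreMiRNA
from .stats import TestResult, chi2_2x2, welch_t


@dataclass
class Cluster:
    members: list[str]
    scaffold: str
    strand: str
    start: int
    end: int
    class_label: str | None = None  # conserved | non-conserved | mixed

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        return cluster_density(self)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    unclustered: list[str] = field(default_factory=list)

    def member_sets(self) -> list[frozenset]:
        return [frozenset(c.members) for c in self.clusters]

    def clustered_ids(self) -> set:
        return {m for c in self.clusters for m in c.members}


def detect_clusters(premirnas: list[PreMiRNA], max_gap: int = 5000) -> ClusterSet:
    """Chain same-scaffold, same-strand precursors with gaps < ``max_gap``.

    Only chains of >= 2 members are clusters; singletons are reported as
    unclustered.
    """
    groups: dict[tuple, list[PreMiRNA]] = {}
    for p in premirnas:
        groups.setdefault((p.interval.scaffold, p.interval.strand), []).append(p)
    clusters, unclustered = [], []
    for (scaffold, strand), members in sorted(groups.items()):
        members.sort(key=lambda p: (p.interval.start, p.interval.end, p.id))
        chain: list[PreMiRNA] = []
        chain_end = None

        def flush():
            if len(chain) >= 2:
                clusters.append(
                    Cluster(
                        members=[p.id for p in chain],
                        scaffold=scaffold,
                        strand=strand,
                        start=min(p.interval.start for p in chain),
                        end=max(p.interval.end for p in chain),
                    )
                )
            elif chain:
                unclustered.append(chain[0].id)

        for p in members:
            if chain and p.interval.start - chain_end < max_gap:
                chain.append(p)
                chain_end = max(chain_end, p.interval.end)
            else:
                flush()
                chain = [p]
                chain_end = p.interval.end
        flush()
    clusters.sort(key=lambda c: (c.scaffold, c.start, c.strand))
    return ClusterSet(clusters=clusters, unclustered=sorted(unclustered))


def cluster_density(cluster: Cluster) -> float:
    """Members per kilobase of cluster span (first start to last end)."""
    if len(cluster.members) < 2:
        raise ValueError("density is undefined for singleton clusters")
    return len(cluster.members) / (cluster.span_bp / 1000.0)


def label_clusters(clusterset: ClusterSet, class_of: dict[str, str]) -> None:
    """Attach a conservation label per cluster.

    A cluster is labeled with its members' shared class, or "mixed" when
    members disagree; mixed clusters are excluded from density comparisons.
    """
    for c in clusterset.clusters:
        labels = {class_of[m] for m in c.members}
        c.class_label = labels.pop() if len(labels) == 1 else "mixed"


def clustered_fraction_test(
    class_of: dict[str, str], clusterset: ClusterSet
) -> tuple[list[list[int]], TestResult]:
    """2x2 (class x clustered?) table with a Yates chi-square.

    ``class_of`` must label every pre-miRNA as conserved or non-conserved.
    """
    clustered = clusterset.clustered_ids()
    table = [[0, 0], [0, 0]]
    for pid, cls in class_of.items():
        if cls == "conserved":
            row = 0
        elif cls == "non-conserved":
            row = 1
        else:
            raise ValueError(f"{pid}: class must be conserved/non-conserved")
        table[row][0 if pid in clustered else 1] += 1
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        raise ValueError("a conservation class is empty")
    return table, chi2_2x2(table, yates=True)


def density_comparison(densities_a, densities_b) -> TestResult:
    """Two-sided Welch t test between two lists of cluster densities."""
    if len(densities_a) < 2 or len(densities_b) < 2:
        raise ValueError("density_comparison requires >= 2 densities per group")
    return welch_t(densities_a, densities_b)
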