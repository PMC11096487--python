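"""Statistical-parsimony haplotype networks, haplogroup classification and
introgressed-sequence counting.

Haplotypes are joined in order of increasing mutational distance as long
as the distance stays within the parsimony connection limit (the largest
number of steps whose probability of a homoplasy-free connection exceeds
the 0.95 threshold).  Connections longer than one step pass through
inferred intermediate nodes; equal-length alternative connections are
retained as reticulations.  Connected components of the resulting graph
are the haplogroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .alignments import HaplotypeTable, split_phase


def parsimony_probability(j: int, L: int) -> float:
    """Probability that two sequences differing at ``j`` of ``L`` sites
    are connected by exactly ``j`` mutations (no superimposed changes).

    The per-site substitution intensity along the connecting path is
    estimated from the observed proportion of differing sites with the
    Jukes-Cantor correction; the probability that each differing site
    experienced exactly one hit, given that it experienced at least one,
    is multiplied over the ``j`` sites.
    """
    if j <= 0:
        return 1.0
    if L < 1:
        raise ValueError("alignment length must be positive")
    p_hat = j / L
    if p_hat >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p_hat / 3.0)
    per_site = lam * math.exp(-lam) / -math.expm1(-lam)
    return per_site ** j


def connection_limit(L: int, p_threshold: float = 0.95,
                     max_steps: int | None = None) -> int:
    """Largest number of mutational steps with parsimony probability at or
    above ``p_threshold``; an explicit ``max_steps`` overrides the
    computation.

    At ``p_threshold=1.0`` no multi-step connection qualifies (the
    probability is strictly below one for any j >= 1), so the limit is 0.
    """
    if max_steps is not None:
        return int(max_steps)
    j = 0
    while parsimony_probability(j + 1, L) >= p_threshold:
        j += 1
        if j > L:
            break
    return j


@dataclass
class ParsimonyNetwork:
    """Haplotype graph with one mutational step per edge.

    Sampled nodes carry ``kind="sampled"`` and per-taxon counts; inferred
    intermediates carry ``kind="inferred"``.
    """

    graph: nx.Graph
    connection_limit: int
    taxon_counts: pd.DataFrame | None = None
    distances: pd.DataFrame | None = None

    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"]

    def components(self) -> list[set[str]]:
        """Connected components restricted to sampled haplotypes, in
        deterministic (smallest-member-first) order."""
        comps = []
        for comp in nx.connected_components(self.graph):
            sampled = {n for n in comp if self.graph.nodes[n]["kind"] == "sampled"}
            if sampled:
                comps.append(sampled)
        return sorted(comps, key=lambda c: min(c))

    def n_inferred(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "inferred")

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(u, v, 1,
                 self.graph.nodes[u]["kind"] == "inferred"
                 or self.graph.nodes[v]["kind"] == "inferred")
                for u, v in sorted(self.graph.edges())]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "steps", "has_inferred"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _haplotype_distances(table: HaplotypeTable) -> pd.DataFrame:
    """Pairwise mutational steps between haplotype character vectors
    (missing characters excluded pairwise)."""
    ids = table.haplotype_ids()
    chars = [table.haplotypes[h] for h in ids]
    k = len(ids)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            steps = sum(1 for a, b in zip(chars[i], chars[j])
                        if a != b and a != "?" and b != "?")
            d[i, j] = d[j, i] = steps
    return pd.DataFrame(d, index=ids, columns=ids)


def build_parsimony_network(table: HaplotypeTable, limit: int,
                            taxon_counts: pd.DataFrame | None = None) -> ParsimonyNetwork:
    """Join haplotypes in order of increasing mutational distance, never
    beyond ``limit`` steps.

    At each distance level every pair that bridges two still-separate
    components is connected (a minimum-spanning construction that keeps
    equal-length alternatives, hence reticulations).  A connection of
    ``d`` steps inserts ``d - 1`` inferred intermediate nodes; the
    intermediates of distinct retained connections are kept separate
    unless they join the same pair of nodes along an identical span.
    """
    ids = table.haplotype_ids()
    g = nx.Graph()
    for hid in ids:
        g.add_node(hid, kind="sampled")
    dist = _haplotype_distances(table)
    pairs = [(int(dist.iloc[i, j]), ids[i], ids[j])
             for i in range(len(ids)) for j in range(i + 1, len(ids))]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    inferred_counter = 0
    for d in sorted({p[0] for p in pairs}):
        if d == 0 or d > limit:
            continue
        level = [p for p in pairs if p[0] == d]
        # component memberships frozen at the start of the level so that
        # equal-length alternatives are all retained
        comp_at_level = {n: i for i, c in enumerate(nx.connected_components(g))
                         for n in c}
        for _, u, v in level:
            if comp_at_level[u] == comp_at_level[v]:
                continue
            if d == 1:
                g.add_edge(u, v)
            else:
                prev = u
                for s in range(1, d):
                    inferred_counter += 1
                    mid = f"i{inferred_counter}"
                    g.add_node(mid, kind="inferred")
                    g.add_edge(prev, mid)
                    prev = mid
                g.add_edge(prev, v)
    return ParsimonyNetwork(graph=g, connection_limit=limit,
                            taxon_counts=taxon_counts, distances=dist)


# --------------------------------------------------------------------------
# haplogroup classification


@dataclass
class HaplogroupAssignment:
    """Haplotype- and sequence-level haplogroup labels."""

    haplotype_labels: dict[str, str]
    sequence_table: pd.DataFrame   # columns: sequence_id, sample, taxon, haplogroup
    warnings: list[str] = field(default_factory=list)

    def counts(self, taxon: str) -> pd.Series:
        sub = self.sequence_table[self.sequence_table["taxon"] == taxon]
        return sub["haplogroup"].value_counts()


def classify_haplogroups(network: ParsimonyNetwork, table: HaplotypeTable,
                         smap: pd.DataFrame, diploid: bool = False,
                         reference_haplotypes: dict[str, str] | None = None
                         ) -> HaplogroupAssignment:
    """Label haplogroups and propagate labels to every sequence.

    By default haplogroups are the network components and each is labelled
    with the majority taxon over its sampled sequence counts (ties broken
    by taxon label order, with a warning).  ``reference_haplotypes``
    (label -> haplotype id) instead seeds labels on user-declared
    reference haplotypes and assigns every haplotype to the label of the
    graph-nearest reference, which supports haplogroup cuts inside one
    connected network.
    """
    taxon_counts = network.taxon_counts
    if taxon_counts is None:
        taxon_counts = table.counts_by(smap, "taxon")
    warnings: list[str] = []
    hap_labels: dict[str, str] = {}

    if reference_haplotypes:
        refs = dict(reference_haplotypes)
        lengths = {}
        for label, ref in refs.items():
            if ref not in network.graph:
                raise ValueError(f"reference haplotype {ref!r} not in network")
            lengths[label] = nx.single_source_shortest_path_length(network.graph, ref)
        for hap in table.haplotype_ids():
            reach = {lab: lengths[lab][hap] for lab in refs if hap in lengths[lab]}
            if not reach:
                hap_labels[hap] = "unconnected"
                continue
            best = min(reach.values())
            cands = sorted(lab for lab, v in reach.items() if v == best)
            if len(cands) > 1:
                warnings.append(f"haplotype {hap}: tie between {cands}, using {cands[0]}")
            hap_labels[hap] = cands[0]
    else:
        used: dict[str, int] = {}
        for comp in network.components():
            counts = taxon_counts.loc[sorted(comp)].sum(axis=0)
            top = counts.max()
            cands = sorted(counts.index[counts == top])
            if len(cands) > 1:
                warnings.append(
                    f"component {sorted(comp)[0]}...: majority tie between "
                    f"{cands}, using {cands[0]}")
            label = cands[0]
            used[label] = used.get(label, 0) + 1
            if used[label] > 1:
                label = f"{label}-{used[label]}"
            for hap in comp:
                hap_labels[hap] = label

    pop_meta = smap.set_index("sample_id")
    rows = []
    for rid, hap in table.assignments.items():
        stem = split_phase(rid)[0] if diploid else rid
        rows.append((rid, stem, pop_meta.loc[stem, "taxon"], hap_labels[hap]))
    seq_table = pd.DataFrame(rows, columns=["sequence_id", "sample", "taxon", "haplogroup"])
    return HaplogroupAssignment(hap_labels, seq_table, warnings)


def count_introgressed(assignment: HaplogroupAssignment, focal_taxon: str,
                       donor_haplogroup: str) -> tuple[int, int, float]:
    """Count focal-taxon sequences that fall in the donor haplogroup.

    Returns ``(count, total, percent)`` with percent rounded to one
    decimal, the resolution at which introgression levels are reported.
    """
    tab = assignment.sequence_table
    if focal_taxon not in set(tab["taxon"]):
        raise ValueError(f"unknown taxon {focal_taxon!r}")
    if donor_haplogroup not in set(assignment.haplotype_labels.values()):
        raise ValueError(f"unknown haplogroup {donor_haplogroup!r}")
    sub = tab[tab["taxon"] == focal_taxon]
    total = len(sub)
    count = int((sub["haplogroup"] == donor_haplogroup).sum())
    percent = round(100.0 * count / total, 1)
    return count, total, percent
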