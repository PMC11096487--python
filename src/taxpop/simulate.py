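"""Synthetic data with the statistical structure the analyses assume.

Two generators live here.

* A backward-time structured-coalescent simulator for a three-deme
  isolation-with-migration history ((TW, PH), MA) with infinite-sites
  mutations and optional indel events.  It is desk-scale and
  analytically checkable (E[TMRCA] for two lineages in one deme is the
  locus' effective gene-copy number of generations).
* A deterministic fixture builder (:func:`make_fixture`) in which every
  sequence's haplogroup membership is fixed by the recipe, so that
  downstream classify-and-count results are exact.  Migrant lineages are
  injected by the recipe, not sampled.

Default demographic magnitudes follow the study system: effective sizes
16,400 / 6,900 / 2,700 individuals for the mainland, Taiwanese and
Philippine demes, splits at 1.56 and 4.16 million years with 25-year
generations, chloroplast inheritance scalar 0.25 and nuclear scalar 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignments import Alignment

BASES = np.array(list("ACGT"))

#: deme labels of the three-taxon history
MAINLAND, TAIWAN, PHILIPPINES = "MA", "TW", "PH"

GENERATION_YEARS = 25.0


@dataclass
class LocusSpec:
    name: str
    length: int
    mu: float                      # per site per generation
    ploidy: str = "haploid"        # "haploid" | "diploid"
    inheritance_scalar: float = 0.25
    indel_rate: float = 0.0        # events per generation per lineage pair path

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mu < 0 or self.indel_rate < 0:
            raise ValueError("invalid locus specification")

    def gene_copies(self, n_individuals: float) -> float:
        """Effective number of gene copies: 2N times the inheritance
        scalar (N/2 for a paternal haploid organelle, 2N nuclear)."""
        return 2.0 * n_individuals * self.inheritance_scalar


def cp_locus(length: int = 2000, mu: float = 1.67e-6 * GENERATION_YEARS / 2000,
             indel_rate: float = 0.0) -> LocusSpec:
    """Concatenated chloroplast locus; the default per-site rate spreads
    the locus-wide yearly clock over the locus length."""
    return LocusSpec("cp", length, mu, ploidy="haploid",
                     inheritance_scalar=0.25, indel_rate=indel_rate)


def its_locus(length: int = 600, mu: float = 1.24e-6 * GENERATION_YEARS / 600,
              indel_rate: float = 0.0) -> LocusSpec:
    return LocusSpec("its", length, mu, ploidy="diploid",
                     inheritance_scalar=1.0, indel_rate=indel_rate)


@dataclass
class SimulationConfig:
    """Three-deme isolation-with-migration history.

    Times are in generations; ``T1`` is the Taiwan/Philippines split and
    ``T2`` the earlier mainland split (T2 > T1).  ``migration`` holds
    backward-in-time per-lineage movement probabilities per generation,
    keyed ``(from_deme, to_deme)``.  The ancestral deme of TW and PH
    takes the Taiwanese size; the root deme takes the mainland size.
    """

    deme_sizes: dict = field(default_factory=lambda: {
        MAINLAND: 16400.0, TAIWAN: 6900.0, PHILIPPINES: 2700.0})
    T1: float = 1.56e6 / GENERATION_YEARS
    T2: float = 4.16e6 / GENERATION_YEARS
    migration: dict = field(default_factory=dict)
    loci: list[LocusSpec] = field(default_factory=lambda: [cp_locus(), its_locus()])
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.T2 >= self.T1 > 0:
            raise ValueError("need T2 >= T1 > 0")
        if any(v < 0 for v in self.migration.values()):
            raise ValueError("migration rates must be non-negative")
        if any(n <= 0 for n in self.deme_sizes.values()):
            raise ValueError("deme sizes must be positive")


@dataclass
class Genealogy:
    """Coalescent tree: arrays indexed by node; leaves come first."""

    parent: np.ndarray      # -1 for the root
    time: np.ndarray
    leaf_names: list[str]
    leaf_demes: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                bl[i] = self.time[p] - self.time[i]
        return bl

    def tmrca(self) -> float:
        return float(self.time.max())


def simulate_genealogy(config: SimulationConfig, locus: LocusSpec,
                       sample_sizes: dict, rng=None, seed=None) -> Genealogy:
    """Backward-time structured coalescent for one locus.

    ``sample_sizes`` maps deme -> number of sampled lineages (gene
    copies).  Exponential waiting times between events; competing risks
    are within-deme coalescence (pair rate 1 / gene copies) and backward
    migration.  At T1 the TW and PH demes merge; at T2 everything merges
    into the root deme, where coalescence to a single lineage is certain.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    copies = {d: locus.gene_copies(n) for d, n in config.deme_sizes.items()}
    anc1 = "_ANC1"
    copies[anc1] = locus.gene_copies(config.deme_sizes[TAIWAN])
    root = "_ROOT"
    copies[root] = locus.gene_copies(config.deme_sizes[MAINLAND])

    leaf_names, leaf_demes = [], []
    lineage_deme, lineage_node = [], []
    for deme in sorted(sample_sizes):
        for i in range(sample_sizes[deme]):
            name = f"{deme}{i + 1:03d}"
            leaf_names.append(name)
            leaf_demes.append(deme)
            lineage_deme.append(deme)
            lineage_node.append(len(lineage_node))
    n = len(leaf_names)
    parent = list([-1] * n)
    times = list([0.0] * n)

    t = 0.0
    epoch_ends = [config.T1, config.T2, math.inf]
    epoch = 0
    while len(lineage_node) > 1:
        active = sorted(set(lineage_deme))
        rates = []
        for d in active:
            k = lineage_deme.count(d)
            if k >= 2:
                rates.append(("coal", d, k * (k - 1) / 2.0 / copies[d]))
        if epoch == 0:
            for (src, dst), m in config.migration.items():
                k = lineage_deme.count(src)
                if k and m > 0 and dst in copies:
                    rates.append(("mig", (src, dst), k * m))
        total = sum(r[2] for r in rates)
        if total == 0:
            wait = math.inf
        else:
            wait = rng.exponential(1.0 / total)
        if t + wait >= epoch_ends[epoch]:
            t = epoch_ends[epoch]
            if epoch == 0:
                lineage_deme = [anc1 if d in (TAIWAN, PHILIPPINES) else d
                                for d in lineage_deme]
            else:
                lineage_deme = [root] * len(lineage_deme)
            epoch += 1
            continue
        t += wait
        u = rng.random() * total
        acc = 0.0
        for kind, what, rate in rates:
            acc += rate
            if u <= acc:
                break
        if kind == "mig":
            src, dst = what
            idxs = [i for i, d in enumerate(lineage_deme) if d == src]
            i = idxs[rng.integers(len(idxs))]
            lineage_deme[i] = dst
        else:
            d = what
            idxs = [i for i, dd in enumerate(lineage_deme) if dd == d]
            pick = rng.choice(len(idxs), size=2, replace=False)
            i, j = sorted((idxs[pick[0]], idxs[pick[1]]), reverse=True)
            new = len(times)
            times.append(t)
            parent.append(-1)
            parent[lineage_node[i]] = new
            parent[lineage_node[j]] = new
            for k_ in sorted((i, j), reverse=True):
                del lineage_node[k_], lineage_deme[k_]
            lineage_node.append(new)
            lineage_deme.append(d)
    return Genealogy(parent=np.array(parent), time=np.array(times),
                     leaf_names=leaf_names, leaf_demes=leaf_demes)


def sprinkle_mutations(genealogy: Genealogy, L: int, mu: float,
                       indel_rate: float = 0.0, rng=None, seed=None,
                       ploidy_mode: str = "haploid") -> Alignment:
    """Place infinite-sites substitutions (Poisson per branch) and
    optional indel events on a genealogy, returning the leaf alignment.

    Raises if more substitutions arise than there are sites (advising a
    longer locus), preserving the infinite-sites idealisation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bl = genealogy.branch_lengths()
    n_mut = rng.poisson(bl * mu * L)
    if n_mut.sum() > L:
        raise ValueError(
            f"{int(n_mut.sum())} mutations exceed {L} sites; use a larger L "
            "for an infinite-sites locus")
    free_sites = list(rng.permutation(L))
    branch_mutations: dict[int, list[int]] = {}
    for node in range(genealogy.n_nodes):
        if n_mut[node]:
            branch_mutations[node] = [free_sites.pop() for _ in range(n_mut[node])]
    branch_indels: dict[int, list[tuple[int, int]]] = {}
    if indel_rate > 0:
        n_ind = rng.poisson(bl * indel_rate)
        for node in range(genealogy.n_nodes):
            for _ in range(n_ind[node]):
                ln = int(rng.integers(1, 4))
                start = int(rng.integers(0, max(1, L - ln)))
                branch_indels.setdefault(node, []).append((start, start + ln))

    children: dict[int, list[int]] = {}
    root = None
    for i, p in enumerate(genealogy.parent):
        if p < 0:
            root = i
        else:
            children.setdefault(int(p), []).append(i)
    ancestral = rng.integers(0, 4, size=L)
    seqs = {root: (ancestral.copy(), [])}
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(children.get(node, []))
    for node in order:
        if node == root:
            continue
        p = genealogy.parent[node]
        seq, gaps = seqs[int(p)]
        seq = seq.copy()
        gaps = list(gaps)
        for site in branch_mutations.get(node, []):
            seq[site] = (seq[site] + 1 + rng.integers(0, 3)) % 4
        gaps.extend(branch_indels.get(node, []))
        seqs[node] = (seq, gaps)

    records = []
    for leaf in range(genealogy.n_leaves):
        seq, gaps = seqs[leaf]
        chars = BASES[seq].copy()
        for s, e in gaps:
            chars[s:e] = "-"
        records.append((genealogy.leaf_names[leaf], "".join(chars)))
    return Alignment(records, ploidy_mode=ploidy_mode)


def simulate_alignment(config: SimulationConfig, locus: LocusSpec,
                       sample_individuals: dict, seed=None) -> tuple[Alignment, pd.DataFrame]:
    """Simulate genealogy + mutations for one locus and build a matching
    sample map.  ``sample_individuals`` maps deme -> individuals; diploid
    loci sample two gene copies per individual (records ``*_h1``/``_h2``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    per_copy = 2 if locus.ploidy == "diploid" else 1
    lineages = {d: n * per_copy for d, n in sample_individuals.items()}
    gen = simulate_genealogy(config, locus, lineages, rng=rng)
    aln = sprinkle_mutations(gen, locus.length, locus.mu, locus.indel_rate,
                             rng=rng)
    rows, records = [], []
    i_leaf = 0
    for deme in sorted(sample_individuals):
        for ind in range(sample_individuals[deme]):
            sample_id = f"{deme}{ind + 1:03d}"
            rows.append((sample_id, deme, deme, per_copy))
            for h in range(per_copy):
                rid, seq = aln.records[i_leaf]
                name = sample_id if per_copy == 1 else f"{sample_id}_h{h + 1}"
                records.append((name, seq))
                i_leaf += 1
    smap = pd.DataFrame(rows, columns=["sample_id", "population", "taxon", "ploidy"])
    mode = "haploid" if per_copy == 1 else "diploid_phased"
    return Alignment(records, ploidy_mode=mode), smap


# --------------------------------------------------------------------------
# deterministic fixtures


@dataclass
class TaxonRecipe:
    """One taxon: its populations (code, individuals) and how many of its
    sequences belong to each haplogroup."""

    name: str
    populations: list
    memberships: dict
    het_excess_populations: tuple = ()

    def n_individuals(self) -> int:
        return sum(n for _, n in self.populations)


@dataclass
class FixtureRecipe:
    """Deterministic dataset blueprint with known haplogroup memberships.

    ``haplotypes_per_group`` seeds that many haplotype variants inside
    each haplogroup (>= 2 whenever heterozygote-excess populations are
    requested); haplogroups are mutually separated by at least
    ``min_between_steps`` mutational steps so a connection limit below
    that splits them into separate networks.
    """

    taxa: list
    ploidy: str = "haploid"
    length: int = 600
    min_between_steps: int = 12
    haplotypes_per_group: int = 2
    within_steps: int = 1

    def seqs_per_individual(self) -> int:
        return 2 if self.ploidy == "diploid_phased" else 1

    def haplogroups(self) -> list[str]:
        out: list[str] = []
        for taxon in self.taxa:
            for hg in taxon.memberships:
                if hg not in out:
                    out.append(hg)
        return out

    def validate(self) -> None:
        k = self.seqs_per_individual()
        for taxon in self.taxa:
            expect = taxon.n_individuals() * k
            got = sum(taxon.memberships.values())
            if expect != got:
                raise ValueError(
                    f"taxon {taxon.name!r}: memberships sum to {got}, "
                    f"but {expect} sequences are sampled")
        needed = len(self.haplogroups()) * (
            self.min_between_steps
            + (self.haplotypes_per_group - 1) * self.within_steps)
        if needed > self.length:
            raise ValueError(
                f"infeasible distance constraints: {needed} distinct mutated "
                f"sites needed but length is {self.length}")


def make_fixture(recipe: FixtureRecipe, seed: int = 0) -> tuple[Alignment, pd.DataFrame, dict]:
    """Build (alignment, sample map, truth) with exact haplogroup counts.

    ``truth`` records each sequence's haplogroup and each haplogroup's
    haplotype ids, so downstream classification can be checked exactly.
    Sequences of different haplogroups differ by at least
    ``2 * min_between_steps`` steps; within a haplogroup by at most
    ``(haplotypes_per_group - 1) * within_steps``.
    """
    recipe.validate()
    rng = np.random.default_rng(seed)
    L = recipe.length
    ancestral = rng.integers(0, 4, size=L)
    site_pool = list(rng.permutation(L))

    hap_seqs: dict[str, list[str]] = {}
    for hg in recipe.haplogroups():
        group_sites = [site_pool.pop() for _ in range(recipe.min_between_steps)]
        base = ancestral.copy()
        for s in group_sites:
            base[s] = (base[s] + 1 + rng.integers(0, 3)) % 4
        variants = ["".join(BASES[base])]
        carrier = base
        for _ in range(recipe.haplotypes_per_group - 1):
            carrier = carrier.copy()
            for _ in range(recipe.within_steps):
                s = site_pool.pop()
                carrier[s] = (carrier[s] + 1 + rng.integers(0, 3)) % 4
            variants.append("".join(BASES[carrier]))
        hap_seqs[hg] = variants

    per_ind = recipe.seqs_per_individual()
    records: list[tuple[str, str]] = []
    map_rows: list[tuple] = []
    truth_seq: dict[str, str] = {}
    for taxon in recipe.taxa:
        seq_stream: list[tuple[str, str]] = []   # (haplogroup, sequence)
        for hg, count in taxon.memberships.items():
            variants = hap_seqs[hg]
            for i in range(count):
                seq_stream.append((hg, variants[i % len(variants)]))
        # introgressed (minority) memberships listed later in the dict end
        # up at the end of the stream; spread them deterministically
        salt = sum(ord(c) * 31 ** i for i, c in enumerate(taxon.name)) % (2 ** 16)
        rng_t = np.random.default_rng(seed + salt)
        order = rng_t.permutation(len(seq_stream))
        seq_stream = [seq_stream[i] for i in order]
        idx = 0
        for pop_code, n_ind in taxon.populations:
            het_excess = pop_code in taxon.het_excess_populations
            for i in range(n_ind):
                sample_id = f"{pop_code}{i + 1:03d}"
                map_rows.append((sample_id, pop_code, taxon.name, per_ind))
                take = seq_stream[idx:idx + per_ind]
                if het_excess and per_ind == 2 and take[0][1] == take[1][1]:
                    hg = take[0][0]
                    variants = hap_seqs[hg]
                    alt = variants[1 % len(variants)]
                    if alt == take[0][1]:
                        alt = variants[0]
                    take = [take[0], (hg, alt)]
                idx += per_ind
                for h, (hg, seq) in enumerate(take):
                    rid = sample_id if per_ind == 1 else f"{sample_id}_h{h + 1}"
                    records.append((rid, seq))
                    truth_seq[rid] = hg
    smap = pd.DataFrame(map_rows, columns=["sample_id", "population", "taxon", "ploidy"])
    aln = Alignment(records, ploidy_mode=recipe.ploidy)
    truth = {"sequence_haplogroup": truth_seq,
             "haplogroup_sequences": hap_seqs}
    return aln, smap, truth


# --------------------------------------------------------------------------
# packaged study-design recipes

TAIWAN_POPULATIONS = [("T", 28), ("N", 16), ("M", 16), ("S", 18), ("H", 15),
                      ("Z", 14), ("C", 15), ("D", 15), ("B", 4)]      # 141
PHILIPPINE_POPULATIONS = [("BH", 18), ("AP", 20)]                     # 38
MAIREI_POPULATIONS = [("HSH", 12), ("LA", 15), ("JY", 15), ("TSH", 15),
                      ("JX", 15), ("WP", 15), ("FQ", 18)]             # 105


def taiwan_cp_recipe() -> FixtureRecipe:
    """Chloroplast design: 2 of 141 Taiwanese sequences sit in the
    mainland (mairei) haplogroup."""
    return FixtureRecipe(
        taxa=[
            TaxonRecipe("mairei", MAIREI_POPULATIONS, {"mairei": 105}),
            TaxonRecipe("taiwanese", TAIWAN_POPULATIONS,
                        {"insular": 139, "mairei": 2}),
        ],
        ploidy="haploid", length=800)


def taiwan_its_recipe() -> FixtureRecipe:
    """ITS design: 16 of 282 Taiwanese phased sequences sit in the
    mainland (mairei) haplogroup."""
    return FixtureRecipe(
        taxa=[
            TaxonRecipe("mairei", MAIREI_POPULATIONS, {"mairei": 210}),
            TaxonRecipe("taiwanese", TAIWAN_POPULATIONS,
                        {"insular": 266, "mairei": 16}),
        ],
        ploidy="diploid_phased", length=800)


def philippines_cp_recipe() -> FixtureRecipe:
    """Chloroplast design: 2 of 38 Philippine sequences belong to the
    recent Taiwan-derived incursion lineage."""
    return FixtureRecipe(
        taxa=[
            TaxonRecipe("taiwanese", TAIWAN_POPULATIONS, {"taiwanese": 141}),
            TaxonRecipe("philippine", PHILIPPINE_POPULATIONS,
                        {"philippine": 36, "taiwanese": 2}),
        ],
        ploidy="haploid", length=800)


def philippines_its_recipe(ap_het_excess: bool = False) -> FixtureRecipe:
    """ITS design: 19 of 76 Philippine phased sequences belong to the
    Taiwan-derived incursion lineage; optionally the AP population is
    built all-heterozygous (the strong heterozygote-excess scenario)."""
    return FixtureRecipe(
        taxa=[
            TaxonRecipe("taiwanese", TAIWAN_POPULATIONS, {"taiwanese": 282}),
            TaxonRecipe("philippine", PHILIPPINE_POPULATIONS,
                        {"philippine": 57, "taiwanese": 19},
                        het_excess_populations=("AP",) if ap_het_excess else ()),
        ],
        ploidy="diploid_phased", length=800)
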