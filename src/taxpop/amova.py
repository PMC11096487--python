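"""Pairwise Phi_ST, hierarchical AMOVA with permutation tests and
neighbour-joining population clustering.

The analysis of molecular variance follows the Excoffier-Smouse-Quattro
sums-of-squared-deviations formulation.  The number of differing
characters between two sequences is used directly as the squared
molecular distance delta^2 (the convention of the standard haplotype
tool-chain).  Negative variance components are retained and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .alignments import Alignment, split_phase


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def sequence_distance_matrix(alignment: Alignment,
                             include_indel_chars: bool = True) -> DistanceMatrix:
    """Pairwise count of differing characters between sequences.

    Substitution differences are counted with pairwise deletion of
    missing characters (N, and gap columns when indel characters are in
    use); each simple-coded indel event adds at most one step per pair.
    """
    from .alignments import code_indels_simple

    mat = np.array([list(s.upper()) for _, s in alignment.records])
    if include_indel_chars:
        indels = code_indels_simple(alignment)
        extra = np.array([list(indels.states[rid]) for rid in alignment.ids]) \
            if indels.n_characters else np.empty((len(alignment.records), 0), dtype="<U1")
        base_missing = np.isin(mat, ["N", "-"])
        mat = np.where(base_missing, "?", mat)
        mat = np.concatenate([mat, extra], axis=1)
    else:
        mat = np.where(mat == "N", "?", mat)
    miss = mat == "?"
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            d[i, j] = d[j, i] = np.sum(mat[i][ok] != mat[j][ok])
    return DistanceMatrix(alignment.ids, d)


# --------------------------------------------------------------------------
# hierarchical AMOVA


@dataclass
class AmovaResult:
    """Variance components, Phi indices and permutation p-values."""

    table: pd.DataFrame          # rows: source of variation
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        return out


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one set of sequences: the mean of
    delta^2 over ordered pairs divided by 2, i.e. sum_{i<j} d2 / n."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _components_from_ssd(d2, groups, pops, individuals=None):
    """Variance components for 3-level (haploid) or 4-level (diploid
    phased, ``individuals`` given) nested designs with unequal sizes."""
    N = d2.shape[0]
    group_ids = sorted(set(groups))
    pop_ids = sorted(set(pops))
    G, P = len(group_ids), len(pop_ids)
    all_idx = np.arange(N)

    ssd_total = _ssd(d2, all_idx)
    ssd_wg = sum(_ssd(d2, np.flatnonzero(np.asarray(groups) == g)) for g in group_ids)
    ssd_wp = sum(_ssd(d2, np.flatnonzero(np.asarray(pops) == p)) for p in pop_ids)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap = ssd_wg - ssd_wp

    m_p = {p: int(np.sum(np.asarray(pops) == p)) for p in pop_ids}
    M_g = {g: int(np.sum(np.asarray(groups) == g)) for g in group_ids}
    pop_group = {}
    for p in pop_ids:
        sel = np.flatnonzero(np.asarray(pops) == p)
        pop_group[p] = groups[sel[0]]

    sum_m2_by_group = {g: 0.0 for g in group_ids}
    for p in pop_ids:
        sum_m2_by_group[pop_group[p]] += m_p[p] ** 2
    A = sum(sum_m2_by_group[g] / M_g[g] for g in group_ids)   # sum_g sum_p m_p^2 / M_g
    B = sum(m_p[p] ** 2 for p in pop_ids) / N                  # sum_p m_p^2 / N
    C = sum(M_g[g] ** 2 for g in group_ids) / N                # sum_g M_g^2 / N

    if individuals is None:
        df = {"among_groups": G - 1, "among_pops": P - G, "within_pops": N - P}
        if df["among_pops"] <= 0 or df["within_pops"] <= 0:
            raise ValueError("degenerate design: need >=2 pops overall and >=2 seqs in pops")
        ms_wp = ssd_wp / df["within_pops"]
        sigma_c = ms_wp
        n_prime = (N - A) / df["among_pops"]
        ms_ap = ssd_ap / df["among_pops"]
        sigma_b = (ms_ap - sigma_c) / n_prime
        rows = {"among_groups": ssd_ag, "among_pops": ssd_ap, "within_pops": ssd_wp}
        if G > 1:
            n_dp = (A - B) / (G - 1)
            n_tp = (N - C) / (G - 1)
            ms_ag = ssd_ag / (G - 1)
            sigma_a = (ms_ag - sigma_c - n_dp * sigma_b) / n_tp
        else:
            sigma_a = np.nan
        comps = {"among_groups": sigma_a, "among_pops": sigma_b, "within_pops": sigma_c}
        return rows, df, comps

    # 4-level: sequences within individuals (2 each) within pops within groups
    ind_ids = sorted(set(individuals))
    I = len(ind_ids)
    ssd_wi = sum(_ssd(d2, np.flatnonzero(np.asarray(individuals) == i)) for i in ind_ids)
    ssd_ai = ssd_wp - ssd_wi
    df = {"among_groups": G - 1, "among_pops": P - G,
          "among_inds": I - P, "within_inds": N - I}
    if min(df["among_pops"], df["among_inds"], df["within_inds"]) <= 0:
        raise ValueError("degenerate design for the 4-level AMOVA")
    sigma_d = ssd_wi / df["within_inds"]
    ms_ai = ssd_ai / df["among_inds"]
    sigma_c = (ms_ai - sigma_d) / 2.0      # exactly 2 sequences per individual
    ms_ap = ssd_ap / df["among_pops"]
    n_prime = (N - A) / df["among_pops"]
    sigma_b = (ms_ap - sigma_d - 2.0 * sigma_c) / n_prime
    rows = {"among_groups": ssd_ag, "among_pops": ssd_ap,
            "among_inds": ssd_ai, "within_inds": ssd_wi}
    if G > 1:
        n_dp = (A - B) / (G - 1)
        n_tp = (N - C) / (G - 1)
        ms_ag = ssd_ag / (G - 1)
        sigma_a = (ms_ag - sigma_d - 2.0 * sigma_c - n_dp * sigma_b) / n_tp
    else:
        sigma_a = np.nan
    comps = {"among_groups": sigma_a, "among_pops": sigma_b,
             "among_inds": sigma_c, "within_inds": sigma_d}
    return rows, df, comps


_LEVEL_LABELS = {
    "among_groups": "Among taxa",
    "among_pops": "Among populations within taxa",
    "among_inds": "Among individuals within populations",
    "within_inds": "Within individuals",
    "within_pops": "Within populations",
}


def _phi_indices(comps) -> dict[str, float]:
    vals = [v for v in comps.values() if not np.isnan(v)]
    total = sum(vals)
    phi = {}
    sa = comps.get("among_groups", np.nan)
    sb = comps["among_pops"]
    if "within_inds" in comps:
        sc, sd = comps["among_inds"], comps["within_inds"]
        lower = sc + sd
        phi["Phi_IS"] = sc / (sc + sd) if (sc + sd) != 0 else np.nan
    else:
        lower = comps["within_pops"]
    if not np.isnan(sa):
        phi["Phi_CT"] = sa / total if total != 0 else np.nan
        phi["Phi_SC"] = sb / (sb + lower) if (sb + lower) != 0 else np.nan
        phi["Phi_ST"] = (sa + sb) / total if total != 0 else np.nan
    else:
        phi["Phi_ST"] = sb / total if total != 0 else np.nan
    return phi


def amova(alignment: Alignment, smap: pd.DataFrame,
          include_indel_chars: bool = True,
          n_permutations: int = 2000, seed: int | None = None,
          distance_matrix: DistanceMatrix | None = None) -> AmovaResult:
    """Hierarchical Phi-statistic AMOVA: taxon / population (/ individual).

    Haploid alignments give the 3-level design (Phi_CT, Phi_SC, Phi_ST);
    phased-diploid alignments add the within-individual level and Phi_IS.
    Permutation schemes per index: whole populations among taxa (Phi_CT),
    individuals among populations within taxa (Phi_SC), individuals among
    all populations (Phi_ST), phased sequences among individuals within
    populations (Phi_IS).
    """
    if distance_matrix is None:
        distance_matrix = sequence_distance_matrix(alignment, include_indel_chars)
    d2 = distance_matrix.values
    diploid = alignment.ploidy_mode == "diploid_phased"
    meta = smap.set_index("sample_id")
    stems = [split_phase(r)[0] if diploid else r for r in alignment.ids]
    pops = np.array([meta.loc[s, "population"] for s in stems])
    groups = np.array([meta.loc[s, "taxon"] for s in stems])
    individuals = np.array(stems) if diploid else None

    warnings = []
    group_sizes = pd.Series(pops).groupby(pd.Series(groups)).nunique()
    if (group_sizes < 2).any() and len(set(groups)) > 1:
        warnings.append(
            "some taxa contain a single population; Phi_CT permutation "
            "test has limited resolution for them"
        )

    rows, df, comps = _components_from_ssd(d2, groups, pops, individuals)
    phi = _phi_indices(comps)

    order = (["among_groups", "among_pops", "among_inds", "within_inds"]
             if diploid else ["among_groups", "among_pops", "within_pops"])
    vals = np.array([comps[k] for k in order])
    total = np.nansum(vals)
    table = pd.DataFrame({
        "source": [_LEVEL_LABELS[k] for k in order],
        "df": [df[k] for k in order],
        "SSD": [rows[k] for k in order],
        "variance": vals,
        "percent": 100.0 * vals / total if total != 0 else np.nan,
    })

    p_values = {}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        p_values = _permutation_pvalues(
            d2, groups, pops, individuals, phi, n_permutations, rng)

    return AmovaResult(table=table, phi=phi, p_values=p_values,
                       n_permutations=n_permutations, seed=seed,
                       warnings=warnings)


def _phi_of(d2, groups, pops, individuals):
    try:
        _, _, comps = _components_from_ssd(d2, groups, pops, individuals)
        return _phi_indices(comps)
    except (ValueError, ZeroDivisionError):
        return {}


def _permutation_pvalues(d2, groups, pops, individuals, phi_obs, n_perm, rng):
    """p = (count(perm >= obs) + 1) / (n_perm + 1) for each Phi index."""
    diploid = individuals is not None
    # permutation units: individuals (blocks of their sequences)
    stems = individuals if diploid else np.arange(len(pops)).astype(str)
    uniq_stems, first_idx = np.unique(stems, return_index=True)
    blocks = {s: np.flatnonzero(stems == s) for s in uniq_stems}
    ind_pop = {s: pops[blocks[s][0]] for s in uniq_stems}
    ind_group = {s: groups[blocks[s][0]] for s in uniq_stems}
    pop_ids = sorted(set(pops))
    pop_group = {p: groups[np.flatnonzero(pops == p)[0]] for p in pop_ids}

    counts = {k: 0 for k in phi_obs}
    for _ in range(n_perm):
        # Phi_ST: permute individuals among all populations
        if "Phi_ST" in phi_obs:
            perm = rng.permutation(uniq_stems)
            new_pops = np.empty_like(pops)
            for src, dst in zip(uniq_stems, perm):
                new_pops[blocks[src]] = ind_pop[dst]
            new_groups = np.array([pop_group[p] for p in new_pops])
            ph = _phi_of(d2, new_groups, new_pops, individuals)
            if ph.get("Phi_ST", -np.inf) >= phi_obs["Phi_ST"] - 1e-12:
                counts["Phi_ST"] += 1
        # Phi_CT: permute whole populations among groups
        if "Phi_CT" in phi_obs:
            labels = np.array([pop_group[p] for p in pop_ids])
            shuffled = rng.permutation(labels)
            remap = dict(zip(pop_ids, shuffled))
            new_groups = np.array([remap[p] for p in pops])
            ph = _phi_of(d2, new_groups, pops, individuals)
            if ph.get("Phi_CT", -np.inf) >= phi_obs["Phi_CT"] - 1e-12:
                counts["Phi_CT"] += 1
        # Phi_SC: permute individuals among populations within their group
        if "Phi_SC" in phi_obs:
            new_pops = pops.copy()
            for g in set(ind_group.values()):
                members = [s for s in uniq_stems if ind_group[s] == g]
                perm = rng.permutation(members)
                for src, dst in zip(members, perm):
                    new_pops[blocks[src]] = ind_pop[dst]
            ph = _phi_of(d2, groups, new_pops, individuals)
            if ph.get("Phi_SC", -np.inf) >= phi_obs["Phi_SC"] - 1e-12:
                counts["Phi_SC"] += 1
        # Phi_IS: permute sequences among individuals within populations
        if "Phi_IS" in phi_obs and diploid:
            new_inds = individuals.copy()
            for p in pop_ids:
                sel = np.flatnonzero(pops == p)
                new_inds[sel] = individuals[sel][rng.permutation(len(sel))]
            ph = _phi_of(d2, groups, pops, new_inds)
            if ph.get("Phi_IS", -np.inf) >= phi_obs["Phi_IS"] - 1e-12:
                counts["Phi_IS"] += 1
    return {k: (c + 1) / (n_perm + 1) for k, c in counts.items()}


# --------------------------------------------------------------------------
# pairwise Phi_ST


def pairwise_phist(seqs_a: list[str], seqs_b: list[str],
                   n_permutations: int = 0, seed: int | None = None):
    """Two-population Phi_ST on raw sequences (character differences as
    delta^2), with an optional sequence-permutation test.

    Returns ``(phi_st, p_value)``; p is None when no permutations run.
    """
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise ValueError("each population needs at least two sequences")
    records = ([(f"a{i}", s) for i, s in enumerate(seqs_a)]
               + [(f"b{i}", s) for i, s in enumerate(seqs_b)])
    aln = Alignment(records)
    d2 = sequence_distance_matrix(aln).values
    pops = np.array(["A"] * len(seqs_a) + ["B"] * len(seqs_b))
    phi = _two_level_phist(d2, pops)
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pops)
            if _two_level_phist(d2, perm) >= phi - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return phi, p


def _two_level_phist(d2: np.ndarray, pops: np.ndarray) -> float:
    _, _, comps = _components_from_ssd(d2, np.repeat("all", len(pops)), pops)
    sb, sw = comps["among_pops"], comps["within_pops"]
    if sb + sw == 0:
        return 0.0
    return sb / (sb + sw)


def phist_matrix(alignment: Alignment, smap: pd.DataFrame,
                 include_indel_chars: bool = True) -> DistanceMatrix:
    """Matrix of pairwise population Phi_ST values (negatives retained)."""
    diploid = alignment.ploidy_mode == "diploid_phased"
    meta = smap.set_index("sample_id")
    stems = [split_phase(r)[0] if diploid else r for r in alignment.ids]
    pops = np.array([meta.loc[s, "population"] for s in stems])
    d2 = sequence_distance_matrix(alignment, include_indel_chars).values
    pop_ids = sorted(set(pops))
    k = len(pop_ids)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sel = np.flatnonzero(np.isin(pops, [pop_ids[i], pop_ids[j]]))
            sub = d2[np.ix_(sel, sel)]
            out[i, j] = out[j, i] = _two_level_phist(sub, pops[sel])
    return DistanceMatrix(pop_ids, out)


# --------------------------------------------------------------------------
# neighbour joining


def nj_tree(dm: DistanceMatrix) -> str:
    """Unrooted neighbour-joining tree (Newick) from a distance matrix.

    Labels are sorted lexicographically before clustering so that ties are
    broken deterministically; negative branch lengths are clamped to zero
    in the output only.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbour joining needs at least three labels")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    sk = _SkbioDM(values, ids=labels)
    tree = _skbio_nj(sk, neg_as_zero=True)
    return str(tree).strip()
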