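"""Per-population diversity statistics, Weir & Cockerham F_IS and the
exact Hardy-Weinberg test.

Missing-data conventions (deliberately DnaSP-like): ``N`` is always
missing; gaps are removed by pairwise deletion for nucleotide diversity
and by complete-column deletion for the segregating-site count behind
Watterson's theta.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING_CHARS = {"N", "-", "?"}


@dataclass
class DiversityResult:
    n: int
    S: int
    L_valid: int
    Hd: float
    pi_per_site: float
    thetaW_per_site: float


@dataclass
class HweResult:
    F_IS: float | None
    p_raw: float
    p_se: float
    n_individuals: int
    n_alleles: int
    method: str  # "enumeration" | "chain"
    chain_steps: int = 0
    burn_in: int = 0
    seed: int | None = None
    p_bonferroni: float | None = None


def haplotype_diversity(counts) -> float:
    """Nei's unbiased gene diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    counts = np.asarray(list(counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least two sequences")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p ** 2)))


def _char_matrix(sequences: list[str]) -> np.ndarray:
    return np.array([list(s.upper()) for s in sequences])


def nucleotide_diversity(sequences: list[str]) -> float:
    """Mean pairwise difference per site, pairwise deletion of gap/N sites.

    Each pair is normalised by its own number of comparable sites and the
    per-pair fractions are averaged over all C(n,2) pairs.
    """
    if len(sequences) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    mat = _char_matrix(sequences)
    valid = ~np.isin(mat, sorted(MISSING_CHARS))
    total = 0.0
    n_pairs = 0
    for i, j in itertools.combinations(range(len(sequences)), 2):
        both = valid[i] & valid[j]
        L_ij = int(both.sum())
        if L_ij == 0:
            raise ValueError(f"sequences {i} and {j} share no comparable sites")
        d_ij = int((mat[i][both] != mat[j][both]).sum())
        total += d_ij / L_ij
        n_pairs += 1
    return total / n_pairs


def segregating_sites(sequences: list[str]) -> tuple[int, int]:
    """(S, L_valid) under complete-column deletion of gap/N columns."""
    mat = _char_matrix(sequences)
    complete = ~np.isin(mat, sorted(MISSING_CHARS)).any(axis=0)
    kept = mat[:, complete]
    L_valid = kept.shape[1]
    S = int(sum(len(set(kept[:, c])) > 1 for c in range(L_valid)))
    return S, L_valid


def watterson_theta(sequences: list[str]) -> float:
    """Watterson's estimator per site: S / (a_{n-1} * L_valid)."""
    n = len(sequences)
    if n < 2:
        raise ValueError("Watterson's theta needs at least two sequences")
    S, L_valid = segregating_sites(sequences)
    if L_valid == 0:
        raise ValueError("no complete columns to analyse")
    a = sum(1.0 / k for k in range(1, n))
    return S / (a * L_valid)


def diversity(sequences: list[str], haplotype_counts=None) -> DiversityResult:
    """Bundle Hd, pi and theta_W for one population sample."""
    n = len(sequences)
    if haplotype_counts is None:
        reps: dict[str, int] = {}
        for s in sequences:
            reps[s] = reps.get(s, 0) + 1
        haplotype_counts = list(reps.values())
    S, L_valid = segregating_sites(sequences)
    return DiversityResult(
        n=n,
        S=S,
        L_valid=L_valid,
        Hd=haplotype_diversity(haplotype_counts),
        pi_per_site=nucleotide_diversity(sequences),
        thetaW_per_site=watterson_theta(sequences),
    )


# --------------------------------------------------------------------------
# F_IS (Weir & Cockerham 1984, single population)


def _allele_stats(genotypes):
    """Allele frequencies and observed heterozygote proportions."""
    n = len(genotypes)
    freqs: dict = {}
    het: dict = {}
    for a, b in genotypes:
        freqs[a] = freqs.get(a, 0) + 1
        freqs[b] = freqs.get(b, 0) + 1
        if a != b:
            het[a] = het.get(a, 0) + 1
            het[b] = het.get(b, 0) + 1
    p = {a: c / (2 * n) for a, c in freqs.items()}
    h = {a: het.get(a, 0) / n for a in freqs}
    return p, h


def fis(genotypes) -> float:
    """Weir & Cockerham's single-population inbreeding coefficient f.

    Per-allele variance components (between individuals, b, and within
    individuals, c) are summed over alleles before forming the ratio, the
    standard multi-allelic combination.  Negative values mean heterozygote
    excess.  Undefined (raises) for monomorphic samples.
    """
    n = len(genotypes)
    if n < 2:
        raise ValueError("F_IS needs at least two individuals")
    p, h = _allele_stats(genotypes)
    if len(p) < 2:
        raise ValueError("F_IS is undefined for a monomorphic sample")
    b_sum = c_sum = 0.0
    for a in p:
        pa, ha = p[a], h[a]
        b = (n / (n - 1.0)) * (pa * (1 - pa) - (2 * n - 1) / (4.0 * n) * ha)
        c = ha / 2.0
        b_sum += b
        c_sum += c
    denom = b_sum + c_sum
    if denom == 0:
        raise ValueError("F_IS denominator is zero")
    return b_sum / denom


# --------------------------------------------------------------------------
# exact HWE test


def _normalise(genotypes):
    return [tuple(sorted(g)) for g in genotypes]


def _table_from_genotypes(genotypes):
    table: dict = {}
    for g in _normalise(genotypes):
        table[g] = table.get(g, 0) + 1
    return table


def _allele_counts(table):
    counts: dict = {}
    for (a, b), k in table.items():
        counts[a] = counts.get(a, 0) + k
        counts[b] = counts.get(b, 0) + k
    return counts


def _log_prob(table, allele_counts, n):
    """log P(genotype table | allele counts) under the exact conditional
    distribution: n! * prod(c_a!) * 2^H / ((2n)! * prod(n_ab!))."""
    H = sum(k for (a, b), k in table.items() if a != b)
    lp = gammaln(n + 1) - gammaln(2 * n + 1) + H * math.log(2.0)
    for c in allele_counts.values():
        lp += gammaln(c + 1)
    for k in table.values():
        lp -= gammaln(k + 1)
    return lp


def _enumerate_tables(allele_counts, cap):
    """All genotype tables consistent with the allele counts, or None if
    more than ``cap`` tables exist."""
    alleles = sorted(allele_counts)
    results = []

    def rec(i, remaining, table):
        if len(results) > cap:
            return False
        if i == len(alleles):
            if all(v == 0 for v in remaining.values()):
                results.append(dict(table))
            return True
        a = alleles[i]
        rest = alleles[i + 1:]

        def distribute(j, left):
            # left copies of allele a to pair with alleles rest[j:] or itself
            if len(results) > cap:
                return False
            if j == len(rest):
                if left % 2 == 0:
                    if left:
                        table[(a, a)] = left // 2
                    rem = dict(remaining)
                    rem[a] = 0
                    ok = rec(i + 1, rem, table)
                    table.pop((a, a), None)
                    if not ok:
                        return False
                return True
            b = rest[j]
            for k in range(0, min(left, remaining[b]) + 1):
                if k:
                    table[(a, b)] = k
                remaining[b] -= k
                ok = distribute(j + 1, left - k)
                remaining[b] += k
                table.pop((a, b), None)
                if not ok:
                    return False
            return True

        return distribute(0, remaining[a])

    ok = rec(0, dict(allele_counts), {})
    if not ok or len(results) > cap:
        return None
    return results


def hwe_exact_pvalue_enumeration(genotypes, cap: int = 100_000):
    """Exact conditional p-value by full enumeration, or None if the table
    universe exceeds ``cap``."""
    table = _table_from_genotypes(genotypes)
    n = len(genotypes)
    counts = _allele_counts(table)
    tables = _enumerate_tables(counts, cap)
    if tables is None:
        return None
    lp_obs = _log_prob(table, counts, n)
    total = prob_le = 0.0
    for t in tables:
        lp = _log_prob(t, counts, n)
        p = math.exp(lp)
        total += p
        if lp <= lp_obs + 1e-9:
            prob_le += p
    return min(1.0, prob_le / total)


def _chain_pvalue(genotypes, steps, burn_in, seed):
    """Allele-shuffling Markov chain estimate of the exact p-value.

    The state is the assignment of the 2n observed allele copies to 2n
    labelled slots (two per individual).  The exact conditional null is
    uniform over these assignments, so transposing two uniformly chosen
    slots each step (always accepted) has exactly the target stationary
    distribution; the p-value is the visit fraction of tables no more
    probable than the observed one.
    """
    rng = np.random.default_rng(seed)
    genos = _normalise(genotypes)
    n = len(genos)
    table = _table_from_genotypes(genos)
    counts = _allele_counts(table)
    lp_obs = _log_prob(table, counts, n)
    lp_cur = lp_obs

    slots = [a for g in genos for a in g]
    hits = np.empty(steps, dtype=bool)
    pick = rng.integers(0, 2 * n, size=(steps + burn_in, 2))
    for t in range(steps + burn_in):
        s1, s2 = pick[t]
        i, j = s1 // 2, s2 // 2
        if i != j and slots[s1] != slots[s2]:
            gi = tuple(sorted((slots[2 * i], slots[2 * i + 1])))
            gj = tuple(sorted((slots[2 * j], slots[2 * j + 1])))
            slots[s1], slots[s2] = slots[s2], slots[s1]
            ni = tuple(sorted((slots[2 * i], slots[2 * i + 1])))
            nj = tuple(sorted((slots[2 * j], slots[2 * j + 1])))
            changes: dict = {}
            for g in (gi, gj):
                changes[g] = changes.get(g, 0) - 1
            for g in (ni, nj):
                changes[g] = changes.get(g, 0) + 1
            for g, dk in changes.items():
                if dk == 0:
                    continue
                k = table.get(g, 0)
                lp_cur += gammaln(k + 1) - gammaln(k + dk + 1)
                if g[0] != g[1]:
                    lp_cur += dk * math.log(2.0)
                table[g] = k + dk
                if table[g] == 0:
                    del table[g]
        if t >= burn_in:
            hits[t - burn_in] = lp_cur <= lp_obs + 1e-9
    p = float(hits.mean())
    n_batches = 20
    batches = np.array_split(hits.astype(float), n_batches)
    means = np.array([b.mean() for b in batches])
    se = float(means.std(ddof=1) / math.sqrt(n_batches))
    return p, se


def hwe_exact_test(genotypes, chain_steps: int = 1_000_000,
                   burn_in: int = 10_000, seed: int | None = None,
                   enumeration_cap: int = 100_000) -> HweResult:
    """Exact test of Hardy-Weinberg proportions conditional on allele counts.

    Full enumeration is used when the genotype-table universe is small
    (<= ``enumeration_cap`` tables); otherwise a Metropolis allele-swap
    Markov chain estimates the same tail probability.  The p-value is the
    total conditional probability of tables no more probable than the one
    observed.
    """
    genos = _normalise(genotypes)
    n = len(genos)
    counts = _allele_counts(_table_from_genotypes(genos))
    n_alleles = len(counts)
    try:
        f = fis(genos)
    except ValueError:
        f = None
    if n_alleles < 2:
        return HweResult(F_IS=f, p_raw=1.0, p_se=0.0, n_individuals=n,
                         n_alleles=n_alleles, method="degenerate")
    p_enum = hwe_exact_pvalue_enumeration(genos, cap=enumeration_cap)
    if p_enum is not None:
        return HweResult(F_IS=f, p_raw=p_enum, p_se=0.0, n_individuals=n,
                         n_alleles=n_alleles, method="enumeration")
    if seed is None:
        raise ValueError("a seed is required for the Markov-chain estimate")
    p, se = _chain_pvalue(genos, chain_steps, burn_in, seed)
    return HweResult(F_IS=f, p_raw=p, p_se=se, n_individuals=n,
                     n_alleles=n_alleles, method="chain",
                     chain_steps=chain_steps, burn_in=burn_in, seed=seed)


def bonferroni(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni correction: per-test threshold alpha/k and adjusted
    p = min(1, k*p)."""
    p = np.asarray(list(p_values), dtype=float)
    k = len(p)
    if k < 1:
        raise ValueError("need at least one p-value")
    return pd.DataFrame({
        "p_raw": p,
        "p_adjusted": np.minimum(1.0, k * p),
        "threshold": alpha / k,
        "significant": p < alpha / k,
    })


# --------------------------------------------------------------------------
# genotype extraction from phased alignments


def genotypes_from_alignment(haplotable, smap: pd.DataFrame) -> dict[str, list[tuple]]:
    """Per-population genotype lists (unordered haplotype-id pairs per
    individual) from a collapsed phased-diploid haplotype table."""
    from .alignments import split_phase

    pop = smap.set_index("sample_id")["population"]
    pairs: dict[str, dict[str, list]] = {}
    for rid, hap in haplotable.assignments.items():
        stem, _ = split_phase(rid)
        pairs.setdefault(pop.loc[stem], {}).setdefault(stem, []).append(hap)
    out = {}
    for popc, by_ind in pairs.items():
        genos = []
        for stem, haps in sorted(by_ind.items()):
            if len(haps) != 2:
                raise ValueError(f"individual {stem!r} has {len(haps)} phased records")
            genos.append(tuple(sorted(haps)))
        out[popc] = genos
    return out
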