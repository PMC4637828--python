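"""Diversity and differentiation statistics.

mtDNA side: haplotype (h) and nucleotide (π) diversity, pairwise sequence
distances, AMOVA variance decomposition (frequency-based F_ST with identity
distances, Φ_ST with sequence distances), permutation p-values.

Microsatellite side: per-locus allele counts / observed and unbiased expected
heterozygosity, Weir & Cockerham's (1984) F_ST estimator θ̂, Jost's (2008)
D_est, and a Raymond–Rousset-style Markov-chain exact test of differentiation
on allele-count contingency tables.

Negative estimates from the unbiased estimators are reported as computed,
never truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .datamodel import DNAProfile, HaplotypeSet


# ---------------------------------------------------------------------------
# distances and diversity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise sequence differences between haplotypes."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    @classmethod
    def identity(cls, labels: Sequence[str]) -> "DistanceMatrix":
        """0 for same haplotype, 1 otherwise — reduces Φ_ST to frequency F_ST."""
        n = len(labels)
        return cls(tuple(labels), np.ones((n, n)) - np.eye(n))


def sequence_distance_matrix(hapset: HaplotypeSet) -> DistanceMatrix:
    """Pairwise counts of differing sites; sites with N in either sequence are
    skipped."""
    names = hapset.names
    arr = np.array([list(hapset[n]) for n in names])
    valid = arr != "N"
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            d[i, j] = d[j, i] = np.count_nonzero(arr[i][ok] != arr[j][ok])
    return DistanceMatrix(tuple(names), d)


def haplotype_and_nucleotide_diversity(
    haplotype_counts: Mapping[str, int],
    distances: DistanceMatrix,
    seq_length: int | None = None,
) -> tuple[float, float]:
    """Unbiased haplotype diversity h and nucleotide diversity π.

    ``h = n(1 − Σ p̂²)/(n − 1)``.  π is the mean pairwise difference over all
    n(n−1)/2 pairs of distinct sampled sequences; when ``seq_length`` is given
    it is reported per site (differences / L), otherwise in differences.
    """
    counts = {k: int(v) for k, v in haplotype_counts.items() if v > 0}
    n = sum(counts.values())
    if n < 2:
        raise ValueError("need at least 2 sampled sequences")
    p = np.array([c / n for c in counts.values()])
    h = n * (1.0 - float((p**2).sum())) / (n - 1)

    labels = list(counts)
    idx = [distances.labels.index(l) for l in labels]
    d = distances.matrix[np.ix_(idx, idx)]
    c = np.array([counts[l] for l in labels], dtype=float)
    # sum of pairwise differences over distinct individual pairs
    total = 0.5 * float(c @ d @ c)  # within-haplotype pairs contribute 0
    pi = total / (n * (n - 1) / 2.0)
    if seq_length is not None:
        pi /= seq_length
    return h, pi


# ---------------------------------------------------------------------------
# microsatellite summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n_typed: int
    n_alleles: int
    ho: float
    he: float


def locus_summary(profiles: Sequence[DNAProfile]) -> list[LocusSummary]:
    """Per-locus allele count, observed heterozygosity Ho and unbiased
    expected heterozygosity He = 2n(1 − Σp̂²)/(2n − 1) (Nei 1978 small-sample
    correction, n = typed individuals)."""
    loci: dict[str, list[tuple[int, int]]] = {}
    for p in profiles:
        for locus, pair in p.genotype.items():
            loci.setdefault(locus, []).append(pair)
    out = []
    for locus in sorted(loci):
        pairs = loci[locus]
        n = len(pairs)
        alleles = [a for pair in pairs for a in pair]
        vals, counts = np.unique(alleles, return_counts=True)
        freqs = counts / (2 * n)
        ho = sum(a != b for a, b in pairs) / n
        if len(vals) == 1:
            he = 0.0
        else:
            he = (2 * n) * (1.0 - float((freqs**2).sum())) / (2 * n - 1)
        out.append(LocusSummary(locus, n, len(vals), ho, he))
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AMOVAResult:
    """Excoffier-style variance decomposition of (squared) genetic distances.

    Two-level runs fill ``sigma_among`` (among strata) and ``sigma_within``;
    three-level runs (with groups of strata) additionally fill
    ``sigma_among_groups``.  Pairwise sequence-difference counts are treated as
    squared Euclidean distances, the Arlequin convention.
    """

    df: tuple[int, ...]
    ss: tuple[float, ...]
    sigma_among_groups: float | None
    sigma_among: float
    sigma_within: float
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None

    @property
    def total_variance(self) -> float:
        return (self.sigma_among_groups or 0.0) + self.sigma_among + self.sigma_within


def _ss_within(d2: np.ndarray, members: Sequence[np.ndarray]) -> float:
    ss = 0.0
    for idx in members:
        if idx.size:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def amova(
    strata: Sequence[str],
    haplotypes: Sequence[str],
    distances: DistanceMatrix | None = None,
    groups: Mapping[str, str] | None = None,
) -> AMOVAResult:
    """AMOVA over individuals carrying one haplotype each.

    Parameters
    ----------
    strata:
        Stratum label per individual (≥ 2 strata, each non-empty).
    haplotypes:
        Haplotype label per individual.
    distances:
        Squared-distance matrix between haplotype labels; ``None`` uses the
        identity distance (0 same / 1 different), in which case Φ_ST equals
        the conventional haplotype-frequency F_ST.
    groups:
        Optional stratum → group mapping for a three-level (among-group /
        among-stratum-within-group / within-stratum) decomposition.
    """
    strata = list(strata)
    haplotypes = list(haplotypes)
    if len(strata) != len(haplotypes):
        raise ValueError("strata and haplotypes must align")
    n_tot = len(strata)
    labels = sorted(set(haplotypes))
    if distances is None:
        distances = DistanceMatrix.identity(labels)
    missing = set(labels) - set(distances.labels)
    if missing:
        raise ValueError(f"haplotypes absent from the distance matrix: {sorted(missing)}")
    hidx = np.array([distances.labels.index(h) for h in haplotypes])
    d2 = distances.matrix[np.ix_(hidx, hidx)]

    pops = sorted(set(strata))
    if len(pops) < 2:
        raise ValueError("need at least 2 strata")
    members = [np.flatnonzero(np.array(strata) == p) for p in pops]
    sizes = np.array([m.size for m in members], dtype=float)
    if np.any(sizes == 0):
        raise ValueError("empty stratum")

    ss_total = d2.sum() / (2.0 * n_tot)
    ss_wp = _ss_within(d2, members)

    if groups is None:
        df_a, df_w = len(pops) - 1, n_tot - len(pops)
        ss_ap = ss_total - ss_wp
        ms_w = ss_wp / df_w if df_w else 0.0
        ms_a = ss_ap / df_a
        n_prime = (n_tot - float((sizes**2).sum()) / n_tot) / df_a
        sigma_w = ms_w
        sigma_a = (ms_a - ms_w) / n_prime
        tot = sigma_a + sigma_w
        phi = sigma_a / tot if tot != 0 else float("nan")
        return AMOVAResult(
            df=(df_a, df_w),
            ss=(ss_ap, ss_wp),
            sigma_among_groups=None,
            sigma_among=sigma_a,
            sigma_within=sigma_w,
            phi_st=phi,
        )

    # three-level decomposition
    gnames = sorted(set(groups[p] for p in pops))
    if len(gnames) < 2:
        raise ValueError("need at least 2 groups for a three-level AMOVA")
    gmembers = {
        g: np.concatenate([m for p, m in zip(pops, members) if groups[p] == g]) for g in gnames
    }
    ss_wg = _ss_within(d2, list(gmembers.values()))  # within groups (pooled strata)
    ss_ap_wg = ss_wg - ss_wp  # among strata within groups
    ss_ag = ss_total - ss_wg

    P, G = len(pops), len(gnames)
    df_ag, df_ap, df_wp = G - 1, P - G, n_tot - P
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap_wg / df_ap
    ms_ag = ss_ag / df_ag

    ng = {g: gmembers[g].size for g in gnames}
    sizes_by_pop = dict(zip(pops, sizes))
    sum_np2_over_ng = sum(
        sum(sizes_by_pop[p] ** 2 for p in pops if groups[p] == g) / ng[g] for g in gnames
    )
    n1 = (n_tot - sum_np2_over_ng) / df_ap
    n2 = (sum_np2_over_ng - float((sizes**2).sum()) / n_tot) / df_ag
    n3 = (n_tot - sum(v**2 for v in ng.values()) / n_tot) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    return AMOVAResult(
        df=(df_ag, df_ap, df_wp),
        ss=(ss_ag, ss_ap_wg, ss_wp),
        sigma_among_groups=sigma_a,
        sigma_among=sigma_b,
        sigma_within=sigma_c,
        phi_st=(sigma_a + sigma_b) / tot if tot != 0 else float("nan"),
        phi_ct=sigma_a / tot if tot != 0 else float("nan"),
        phi_sc=sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else float("nan"),
    )


def multilocus_phi_st(results: Sequence[AMOVAResult]) -> float:
    """Combine per-locus AMOVA runs by summing variance components (the
    standard multi-locus AMOVA combination)."""
    a = sum(r.sigma_among for r in results)
    w = sum(r.sigma_within for r in results)
    return a / (a + w)


# ---------------------------------------------------------------------------
# differentiation results and permutation machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentiationResult:
    statistic: str  # F_ST | Phi_ST | WC_F_ST | Jost_D
    estimate: float
    p_value: float | None = None
    n_resamples: int | None = None
    strata: tuple[str, ...] = ()
    per_locus: Mapping[str, float] = field(default_factory=dict)
    p_std_error: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def permutation_pvalue(
    statistic: Callable[[Sequence[str]], float],
    labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation p-value with add-one smoothing.

    Individuals' stratum labels are permuted; ``p = (#{perm ≥ obs} + 1) /
    (n_perm + 1)``.  Returns ``(observed statistic, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += statistic(rng.permutation(labels)) >= obs - 1e-12
    return obs, (count + 1) / (n_perm + 1)


def pairwise_fst_mtdna(
    strata: Sequence[str],
    haplotypes: Sequence[str],
    distances: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[DifferentiationResult, DifferentiationResult]:
    """Two-stratum (or multi-stratum) mtDNA differentiation: frequency-based
    F_ST (identity distances) and Φ_ST (sequence distances), permutation
    p-values for both."""
    haplotypes = list(haplotypes)
    names = tuple(sorted(set(strata)))

    def stat_fst(lab):
        return amova(lab, haplotypes, None).phi_st

    def stat_phi(lab):
        return amova(lab, haplotypes, distances).phi_st

    fst, p_f = permutation_pvalue(stat_fst, strata, n_perm, seed)
    phi, p_p = permutation_pvalue(stat_phi, strata, n_perm, seed + 1)
    return (
        DifferentiationResult("F_ST", fst, p_f, n_perm, names),
        DifferentiationResult("Phi_ST", phi, p_p, n_perm, names),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_components_locus(
    genotypes_by_pop: Sequence[Sequence[tuple[int, int]]]
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) summed over the
    alleles of one locus.  Populations with no typed individuals are dropped."""
    pops = [list(g) for g in genotypes_by_pop if len(g) > 0]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0, 0.0
    n = np.array([len(g) for g in pops], dtype=float)
    alleles = sorted({a for g in pops for pair in g for a in pair})
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p = np.array([sum(pair.count(al) for pair in g) / (2 * len(g)) for g in pops])
        h = np.array([sum((al in pair) and pair[0] != pair[1] for pair in g) / len(g) for g in pops])
        pbar = float((n * p).sum() / n.sum())
        s2 = float((n * (p - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = float((n * h).sum() / n.sum())
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_fst(
    profiles: Sequence[DNAProfile],
    strata: Mapping[str, Sequence[DNAProfile]] | None = None,
    stratum_of: Callable[[DNAProfile], str] | None = None,
) -> DifferentiationResult:
    """Multi-locus Weir & Cockerham (1984) θ̂.

    Per locus the variance components (a: among populations, b: among
    individuals within populations, c: within individuals) are summed over
    alleles; the multi-locus estimate is ``Σa / Σ(a+b+c)`` over loci.  Missing
    genotypes are excluded per locus.  If every locus is monomorphic the
    estimate is undefined (NaN).
    """
    if strata is None:
        key = stratum_of or (lambda p: p.management_unit)
        strata = {}
        for p in profiles:
            strata.setdefault(key(p), []).append(p)
    pops = sorted(strata)
    if len(pops) < 2:
        raise ValueError("need at least 2 strata")
    loci = sorted({l for ps in strata.values() for p in ps for l in p.genotype})
    a_tot = d_tot = 0.0
    per_locus = {}
    for locus in loci:
        by_pop = [
            [p.genotype[locus] for p in strata[pop] if locus in p.genotype] for pop in pops
        ]
        a, b, c = _wc_components_locus(by_pop)
        denom = a + b + c
        per_locus[locus] = a / denom if denom != 0 else float("nan")
        a_tot += a
        d_tot += denom
    est = a_tot / d_tot if d_tot != 0 else float("nan")
    return DifferentiationResult("WC_F_ST", est, strata=tuple(pops), per_locus=per_locus)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------


def josts_d(
    profiles: Sequence[DNAProfile],
    strata: Mapping[str, Sequence[DNAProfile]] | None = None,
    stratum_of: Callable[[DNAProfile], str] | None = None,
) -> DifferentiationResult:
    """Jost's (2008) D_est per locus, averaged arithmetically across loci.

    Per locus, with r strata and harmonic-mean sample size ñ (typed
    individuals): ``H_S = (ñ/(ñ−1))(1 − mean_k Σ_i p̂_ki²)``,
    ``H_T = 1 − Σ_i p̄_i² + H_S/(rñ)``, and
    ``D = (r/(r−1)) (H_T − H_S)/(1 − H_S)`` (Nei–Chesser unbiased
    heterozygosities).  Monomorphic loci contribute 0.  Small negative values
    from the unbiased estimators are reported as computed.
    """
    if strata is None:
        key = stratum_of or (lambda p: p.management_unit)
        strata = {}
        for p in profiles:
            strata.setdefault(key(p), []).append(p)
    pops = sorted(strata)
    r_all = len(pops)
    if r_all < 2:
        raise ValueError("need at least 2 strata")
    loci = sorted({l for ps in strata.values() for p in ps for l in p.genotype})
    per_locus = {}
    for locus in loci:
        freqs, ns = [], []
        for pop in pops:
            pairs = [p.genotype[locus] for p in strata[pop] if locus in p.genotype]
            if not pairs:
                continue
            alleles = [a for pair in pairs for a in pair]
            ns.append(len(pairs))
            freqs.append(alleles)
        r = len(freqs)
        if r < 2:
            continue
        allele_set = sorted({a for f in freqs for a in f})
        if len(allele_set) < 2:
            per_locus[locus] = 0.0
            continue
        P = np.zeros((r, len(allele_set)))
        for k, alleles in enumerate(freqs):
            vals, counts = np.unique(alleles, return_counts=True)
            for v, c in zip(vals, counts):
                P[k, allele_set.index(v)] = c / (2 * ns[k])
        n_harm = r / np.sum(1.0 / np.asarray(ns, dtype=float))
        hs_raw = 1.0 - float((P**2).sum(axis=1).mean())
        hs = (2 * n_harm / (2 * n_harm - 1)) * hs_raw
        pbar = P.mean(axis=0)
        ht = 1.0 - float((pbar**2).sum()) + hs / (2 * n_harm * r)
        denom = 1.0 - hs
        per_locus[locus] = (
            (r / (r - 1)) * (ht - hs) / denom if denom != 0 else 1.0
        )
    vals = [v for v in per_locus.values()]
    est = float(np.mean(vals)) if vals else 0.0
    return DifferentiationResult("Jost_D", est, strata=tuple(pops), per_locus=per_locus)


# ---------------------------------------------------------------------------
# exact test of differentiation (Markov chain over contingency tables)
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """log P(table | margins) up to a constant: −Σ log(x_ij!)."""
    return -float(gammaln(table + 1.0).sum())


def exact_g_test_mcmc(
    table: Sequence[Sequence[int]],
    n_steps: int = 100_000,
    n_dememorization: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Exact test of differentiation on an allele/haplotype × population
    count table (Raymond & Rousset style).

    A Metropolis Markov chain walks the space of tables with the observed
    margins (±1 checkerboard moves on random 2×2 subtables); the p-value is
    the chain fraction of tables no more probable than the observed table
    under the conditional multivariate hypergeometric distribution.  Returns
    ``(p, standard error of p)`` with the SE from batch means.

    Degenerate margins (a single row or column) give p = 1.
    """
    x = np.array(table, dtype=np.int64)
    if x.ndim != 2 or np.any(x < 0):
        raise ValueError("table must be a nonnegative 2-D count array")
    x = x[x.sum(axis=1) > 0][:, x.sum(axis=0) > 0]
    nr, nc = x.shape
    if nr < 2 or nc < 2:
        return 1.0, 0.0

    rng = np.random.default_rng(seed)
    obs_lp = _log_table_prob(x)
    cur = x.copy()
    cur_lp = obs_lp

    total = n_dememorization + n_steps
    rows = rng.integers(nr, size=total)
    rows2 = rng.integers(nr, size=total)
    cols = rng.integers(nc, size=total)
    cols2 = rng.integers(nc, size=total)
    us = rng.random(total)

    at_most = 0
    batches: list[float] = []
    batch_n = max(n_steps // 20, 1)
    batch_count = 0
    batch_hits = 0
    eps = 1e-9
    for t in range(total):
        i1, i2, j1, j2 = rows[t], rows2[t], cols[t], cols2[t]
        if i1 != i2 and j1 != j2:
            # move a unit: (i1,j1),(i2,j2) += 1 ; (i1,j2),(i2,j1) -= 1
            if cur[i1, j2] > 0 and cur[i2, j1] > 0:
                log_ratio = (
                    np.log(cur[i1, j2]) + np.log(cur[i2, j1])
                    - np.log(cur[i1, j1] + 1.0) - np.log(cur[i2, j2] + 1.0)
                )
                if log_ratio >= 0 or us[t] < np.exp(log_ratio):
                    cur[i1, j1] += 1
                    cur[i2, j2] += 1
                    cur[i1, j2] -= 1
                    cur[i2, j1] -= 1
                    cur_lp += log_ratio
        if t >= n_dememorization:
            hit = cur_lp <= obs_lp + eps
            at_most += hit
            batch_hits += hit
            batch_count += 1
            if batch_count == batch_n:
                batches.append(batch_hits / batch_n)
                batch_hits = 0
                batch_count = 0
    p = at_most / n_steps
    if len(batches) > 1:
        se = float(np.std(batches, ddof=1) / np.sqrt(len(batches)))
    else:
        se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_steps))
    return float(p), se
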