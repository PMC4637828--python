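"""Isotope–genetics association tests for maternally directed migratory culture.

If whales learn their feeding destination from their mothers, whales sharing a
matriline (mtDNA haplotype, here within a management unit) should have more
similar feeding-ground isotope signatures (δ13C) than whales from different
matrilines, and closer kin should be isotopically closer.  This module holds
the test battery:

* Kruskal–Wallis rank test of isotope values across haplotypes;
* Gaussian linear-model ranking by AIC / Akaike weights over all subsets of
  {haplotype, sex, state} with optional two-way interactions;
* the matriline randomization test: observed between/within-group mean-square
  F-ratio against its label-permutation null, p as the plain proportion of
  randomized F-values at least as extreme;
* Ritland (1996) and Lynch & Ritland (1999) pairwise relatedness from
  microsatellites, and Mantel tests of relatedness-derived distance against
  isotopic Euclidean distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DNAProfile, IsotopeProfile


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from the χ² approximation.

    ``groups`` is a sequence of value arrays, one per mtDNA haplotype (or any
    grouping).  All values identical → H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((t**3 - t).sum()) / (n**3 - n))
    h /= tie
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass(frozen=True)
class ModelWeightTable:
    """AIC ranking of candidate linear models.

    ``models`` rows: (terms, k_params, aic, delta_aic, weight); ``factor_weights``
    maps each main-effect factor to the summed Akaike weight of the models that
    include it.
    """

    models: pd.DataFrame
    factor_weights: Mapping[str, float]


def _design_matrix(df: pd.DataFrame, mains: Sequence[str], inters: Sequence[tuple[str, str]]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for f in mains:
        d = pd.get_dummies(df[f].astype("category"), drop_first=True)
        cols.append(d.to_numpy(dtype=float))
    for a, b in inters:
        da = pd.get_dummies(df[a].astype("category"), drop_first=True).to_numpy(dtype=float)
        db = pd.get_dummies(df[b].astype("category"), drop_first=True).to_numpy(dtype=float)
        cols.append(np.einsum("ni,nj->nij", da, db).reshape(len(df), -1))
    return np.column_stack(cols)


def glm_aic_weights(
    response: Sequence[float],
    factors: Mapping[str, Sequence],
    include_interactions: bool = True,
    use_aicc: bool = False,
) -> ModelWeightTable:
    """Rank Gaussian linear models of an isotope response by AIC.

    Candidates: every subset of the main-effect factors (including the
    intercept-only model), and — when ``include_interactions`` — every subset
    of the two-way interactions among each model's included mains.  AIC uses
    the Gaussian log-likelihood with the ML variance estimate
    (``n·ln(RSS/n) + n·ln 2π + n + 2k``).  Akaike weights are
    ``exp(−Δᵢ/2)`` normalised over the candidate set; the summed weight per
    factor is reported.  Models with singular (aliased) designs are dropped
    with a warning; any model must satisfy n > parameters.
    """
    y = np.asarray(response, dtype=float)
    df = pd.DataFrame({k: list(v) for k, v in factors.items()}, index=range(y.size))
    if any(len(list(v)) != y.size for v in factors.values()):
        raise ValueError("response and factors must align")
    names = list(factors)
    rows = []
    for k in range(len(names) + 1):
        for mains in itertools.combinations(names, k):
            pairs = list(itertools.combinations(mains, 2)) if include_interactions else []
            for j in range(len(pairs) + 1):
                for inters in itertools.combinations(pairs, j):
                    X = _design_matrix(df, mains, inters)
                    if X.shape[1] >= y.size:
                        warnings.warn(
                            f"model {mains}+{inters} has >= n parameters; dropped"
                        )
                        continue
                    if np.linalg.matrix_rank(X) < X.shape[1]:
                        warnings.warn(f"model {mains}+{inters} is aliased; dropped")
                        continue
                    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                    rss = float(((y - X @ beta) ** 2).sum())
                    n = y.size
                    kpar = X.shape[1] + 1  # + residual variance
                    aic = n * np.log(max(rss, 1e-300) / n) + n * np.log(2 * np.pi) + n + 2 * kpar
                    if use_aicc:
                        if n - kpar - 1 <= 0:
                            continue
                        aic += 2 * kpar * (kpar + 1) / (n - kpar - 1)
                    term_label = " + ".join(
                        list(mains) + [f"{a}:{b}" for a, b in inters]
                    ) or "1"
                    rows.append(
                        {"terms": term_label, "mains": mains, "k": kpar, "aic": aic}
                    )
    if not rows:
        raise ValueError("no estimable candidate model")
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = np.exp(-0.5 * table["delta_aic"].to_numpy())
    table["weight"] = w / w.sum()
    table = table.sort_values("aic", ignore_index=True)
    factor_weights = {
        f: float(table.loc[[f in m for m in table["mains"]], "weight"].sum()) for f in names
    }
    return ModelWeightTable(models=table.drop(columns=["mains"]), factor_weights=factor_weights)


# ---------------------------------------------------------------------------
# matriline randomization test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatrilineGrouping:
    """individual sample_id -> matriline label (haplotype, management_unit)."""

    labels: Mapping[str, tuple[str, str]]

    @classmethod
    def from_profiles(cls, profiles: Sequence[DNAProfile]) -> "MatrilineGrouping":
        return cls(
            {p.sample_id: (p.haplotype, p.management_unit) for p in profiles if p.haplotype}
        )


def _f_ratio(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    gsum = np.bincount(codes, weights=values, minlength=n_groups)
    gn = np.bincount(codes, minlength=n_groups).astype(float)
    grand = values.sum()
    ssb = float((gsum**2 / gn).sum() - grand**2 / n)
    sst = float((values**2).sum() - grand**2 / n)
    ssw = sst - ssb
    msb = ssb / (n_groups - 1)
    msw = ssw / (n - n_groups)
    if msw == 0:
        return float("inf") if msb > 0 else float("nan")
    return msb / msw


def matriline_randomization_test(
    values: Sequence[float],
    groups: Sequence,
    n_rand: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Randomization test of isotopic similarity within matrilines.

    The observed F-ratio (between- to within-group mean squares of the isotope
    values grouped by matriline) is compared with its distribution under
    ``n_rand`` random permutations of the group labels.  The p-value is the
    plain proportion of randomized F-values as extreme or more extreme than
    the observed one (no add-one smoothing; infinities compare as equal
    extremes).  Returns ``(F, p)``.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    values = np.asarray(values, dtype=float)
    label_index: dict = {}
    codes = np.array([label_index.setdefault(g, len(label_index)) for g in groups])
    n_groups = len(label_index)
    if n_groups < 2 or values.size < n_groups + 1:
        raise ValueError("need >= 2 groups and more observations than groups")

    obs = _f_ratio(values, codes, n_groups)
    rng = np.random.default_rng(seed)

    # permute values against fixed labels (equivalent to permuting labels)
    perms = np.argsort(rng.random((n_rand, values.size)), axis=1)
    V = values[perms]  # (n_rand, n)
    M = np.zeros((values.size, n_groups))
    M[np.arange(values.size), codes] = 1.0
    gn = M.sum(axis=0)
    gsum = V @ M
    grand = values.sum()
    n = values.size
    ssb = (gsum**2 / gn).sum(axis=1) - grand**2 / n
    sst = float((values**2).sum() - grand**2 / n)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f_rand = (ssb / (n_groups - 1)) / (ssw / (n - n_groups))
    p = float(np.mean(f_rand >= obs - 1e-12)) if np.isfinite(obs) else float(
        np.mean(~np.isfinite(f_rand) | (f_rand == np.inf))
    )
    return float(obs), p


# ---------------------------------------------------------------------------
# relatedness estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelatednessMatrix:
    """Pairwise relatedness estimates, pair-averaged (symmetric), NaN diagonal."""

    estimator: str
    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    reference_freqs: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.matrix[i, j])

    def pairs(self) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                out.append((self.sample_ids[i], self.sample_ids[j], float(self.matrix[i, j])))
        return out


def _freq_shares(genotype: tuple[int, int], alleles: list[int]) -> np.ndarray:
    f = np.zeros(len(alleles))
    f[alleles.index(genotype[0])] += 0.5
    f[alleles.index(genotype[1])] += 0.5
    return f


def _ritland_locus(gx, gy, alleles: list[int], p: np.ndarray) -> tuple[float, float] | None:
    """Ritland (1996): r̂ = 2/(k−1) · (Σ_i f_xi f_yi / p_i − 1); weight k−1."""
    k = len(alleles)
    if k < 2:
        return None
    fx = _freq_shares(gx, alleles)
    fy = _freq_shares(gy, alleles)
    s = float((fx * fy / p).sum())
    return (2.0 / (k - 1)) * (s - 1.0), float(k - 1)


def _lynch_ritland_locus(gx, gy, alleles: list[int], p: np.ndarray) -> tuple[float, float] | None:
    """Lynch & Ritland (1999) with reference individual x = (a, b):

    r̂ = [p_a(S_bc+S_bd) + p_b(S_ac+S_ad) − 4 p_a p_b]
        / [(1+S_ab)(p_a+p_b) − 4 p_a p_b]

    returned as (numerator/denominator, weight = denominator/(2 p_a p_b)); the
    weighted multi-locus combination then reduces to Σnum/(2p_ap_b) / Σw.
    """
    a, b = gx
    c, d = gy
    pa, pb = p[alleles.index(a)], p[alleles.index(b)]
    s_ab = float(a == b)
    num = pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d)) - 4 * pa * pb
    den = (1 + s_ab) * (pa + pb) - 4 * pa * pb
    if den == 0 or pa * pb == 0:
        return None
    w = den / (2 * pa * pb)
    return num / den, w


def relatedness_estimates(
    profiles: Sequence[DNAProfile],
    estimator: str = "ritland",
    allele_freqs: Mapping[str, Mapping[int, float]] | None = None,
    min_shared_loci: int = 2,
) -> RelatednessMatrix:
    """Pairwise relatedness matrix from microsatellite genotypes.

    ``estimator`` is ``"ritland"`` or ``"lynch_ritland"``; both are
    moment estimators referenced to population allele frequencies (by default
    computed from the full supplied sample, the COANCESTRY convention).
    Per-locus estimates are combined with each estimator's own locus weights;
    the Lynch–Ritland estimator is asymmetric in (reference, proband) and is
    averaged over the two orderings.  Pairs sharing fewer than
    ``min_shared_loci`` typed loci are NaN.

    Raises if a genotype carries an allele absent from the reference
    frequencies (naming locus and allele).
    """
    from .qc import allele_frequencies

    estimator = estimator.lower()
    if estimator not in ("ritland", "lynch_ritland"):
        raise ValueError("estimator must be 'ritland' or 'lynch_ritland'")
    profiles = list(profiles)
    if allele_freqs is None:
        allele_freqs = allele_frequencies(profiles)
    ref = {
        locus: (sorted(d), np.array([d[a] for a in sorted(d)], dtype=float))
        for locus, d in allele_freqs.items()
    }
    for p in profiles:
        for locus, pair in p.genotype.items():
            if locus not in ref:
                raise ValueError(f"locus {locus!r} absent from reference frequencies")
            for al in pair:
                if al not in ref[locus][0]:
                    raise ValueError(
                        f"allele {al} at locus {locus!r} absent from reference frequencies"
                    )

    n = len(profiles)
    mat = np.full((n, n), np.nan)
    per_locus_fn = _ritland_locus if estimator == "ritland" else _lynch_ritland_locus
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(profiles[i].genotype) & set(profiles[j].genotype))
            if len(shared) < min_shared_loci:
                continue
            ests = []
            for ordering in ((i, j), (j, i)):
                num = den = 0.0
                any_locus = False
                for locus in shared:
                    alleles, p = ref[locus]
                    out = per_locus_fn(
                        profiles[ordering[0]].genotype[locus],
                        profiles[ordering[1]].genotype[locus],
                        alleles,
                        p,
                    )
                    if out is None:
                        continue
                    r_l, w_l = out
                    num += w_l * r_l
                    den += w_l
                    any_locus = True
                if any_locus and den != 0:
                    ests.append(num / den)
            if ests:
                mat[i, j] = mat[j, i] = float(np.mean(ests))
    return RelatednessMatrix(
        estimator=estimator,
        sample_ids=tuple(p.sample_id for p in profiles),
        matrix=mat,
        reference_freqs=allele_freqs,
    )


# ---------------------------------------------------------------------------
# isotope distances and Mantel test
# ---------------------------------------------------------------------------


def isotope_distance_matrix(
    isotopes: Sequence[IsotopeProfile], channels: Sequence[str] = ("d13C",)
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise Euclidean distance between isotope profiles over the selected
    channels (single channel = absolute difference).  Individuals missing any
    selected channel are excluded with a warning."""
    rows, ids = [], []
    for ip in isotopes:
        vals = [getattr(ip, ch) for ch in channels]
        if any(v is None for v in vals):
            warnings.warn(f"sample {ip.sample_id!r} missing {list(channels)}; excluded")
            continue
        rows.append(vals)
        ids.append(ip.sample_id)
    X = np.asarray(rows, dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    return tuple(ids), np.sqrt((diff**2).sum(axis=2))


def relatedness_to_distance(rel: RelatednessMatrix) -> np.ndarray:
    """Monotone-decreasing transform max(r) − r, turning relatedness into a
    dissimilarity for Mantel tests (higher kinship ↔ smaller distance)."""
    m = rel.matrix.copy()
    off = ~np.eye(m.shape[0], dtype=bool)
    mx = np.nanmax(m[off])
    d = mx - m
    np.fill_diagonal(d, 0.0)
    return d


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two symmetric distance matrices.

    r is the Pearson correlation of the off-diagonal entries; significance by
    simultaneously permuting the rows and columns of ``b`` (add-one smoothed).
    ``alternative='greater'`` tests for positive association — with matrix a =
    relatedness-derived distance and b = isotopic distance this is the
    "higher relatedness ↔ smaller isotopic distance" direction.  Pairs that
    are NaN in either matrix are excluded from the correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(bm: np.ndarray) -> float:
        x, y = a[iu], bm[iu]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    obs = corr(b)
    if not np.isfinite(obs):
        raise ValueError("Mantel correlation undefined (constant or empty matrix)")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r >= obs - 1e-12
        elif alternative == "less":
            count += r <= obs + 1e-12
        else:
            count += abs(r) >= abs(obs) - 1e-12
    return obs, (count + 1) / (n_perm + 1)
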