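"""Genotype quality control.

Error-rate bookkeeping from internal amplification controls, probability of
identity (P_ID), duplicate-genotype detection and per-stratum removal, and a
Monte-Carlo exact test of Hardy–Weinberg equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .datamodel import DNAProfile


@dataclass(frozen=True)
class ErrorRate:
    n_allele_calls: int
    n_errors: int

    @property
    def proportion(self) -> float:
        return self.n_errors / self.n_allele_calls

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def per_allele_error_rate(n_allele_calls: int, n_errors: int) -> ErrorRate:
    """Per-allele genotyping error rate from repeat-amplification controls.

    ``rate = n_errors / n_allele_calls``; exposed both as a proportion and as
    a percentage.
    """
    if n_allele_calls <= 0:
        raise ValueError("n_allele_calls must be positive")
    if n_errors < 0 or n_errors > n_allele_calls:
        raise ValueError("n_errors must be between 0 and n_allele_calls")
    return ErrorRate(n_allele_calls, n_errors)


def probability_of_identity(
    allele_freqs: Mapping[str, Sequence[float]], loci: Sequence[str] | None = None
) -> float:
    """Multi-locus probability of identity for unrelated individuals.

    Per locus ``P_ID = Σ p_i^4 + Σ_{i<j} (2 p_i p_j)^2``; multi-locus P_ID is
    the product over loci (independence across loci).
    """
    if loci is None:
        loci = sorted(allele_freqs)
    loci = list(loci)
    if not loci:
        raise ValueError("empty locus set")
    total = 1.0
    for locus in loci:
        p = np.asarray(allele_freqs[locus], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {locus!r}: allele frequencies sum to {p.sum()}, not 1")
        # Σp^4 + Σ_{i<j}(2 p_i p_j)^2 = 2(Σp²)² − Σp⁴
        s2, s4 = float((p**2).sum()), float((p**4).sum())
        total *= 2.0 * s2**2 - s4
    return total


def allele_frequencies(profiles: Sequence[DNAProfile]) -> dict[str, dict[int, float]]:
    """Observed allele frequencies per locus over typed individuals."""
    counts: dict[str, dict[int, int]] = {}
    for p in profiles:
        for locus, (a, b) in p.genotype.items():
            d = counts.setdefault(locus, {})
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
    return {
        locus: {al: c / sum(d.values()) for al, c in sorted(d.items())}
        for locus, d in counts.items()
    }


@dataclass(frozen=True)
class DuplicateReport:
    """A genotype match between two samples."""

    pair: tuple[str, str]
    loci_compared: int
    loci_matching: int
    mismatches: int
    p_id: float

    def __post_init__(self) -> None:
        if self.loci_matching > self.loci_compared:
            raise ValueError("loci_matching cannot exceed loci_compared")


def find_duplicates(
    profiles: Sequence[DNAProfile],
    min_shared_loci: int = 8,
    max_mismatch: int = 1,
) -> list[DuplicateReport]:
    """All sample pairs whose genotypes match at the shared typed loci.

    A pair is reported when ≥ ``min_shared_loci`` loci are typed in both
    profiles and at most ``max_mismatch`` of them disagree.  Each report
    carries the multi-locus P_ID of the matching loci, computed from the
    observed allele frequencies of the full sample — the chance that two
    unrelated individuals would share that profile.  Reports are ordered by
    (id, id); flagged pairs are reported, never auto-merged.
    """
    if min_shared_loci < 1:
        raise ValueError("min_shared_loci must be >= 1")
    freqs = {
        locus: list(d.values()) for locus, d in allele_frequencies(profiles).items()
    }
    ordered = sorted(profiles, key=lambda p: p.sample_id)
    reports = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            shared = sorted(set(a.genotype) & set(b.genotype))
            if len(shared) < min_shared_loci:
                continue
            matching = [l for l in shared if a.genotype[l] == b.genotype[l]]
            mism = len(shared) - len(matching)
            if mism > max_mismatch:
                continue
            pid = probability_of_identity(freqs, matching) if matching else 1.0
            reports.append(
                DuplicateReport(
                    pair=(a.sample_id, b.sample_id),
                    loci_compared=len(shared),
                    loci_matching=len(matching),
                    mismatches=mism,
                    p_id=pid,
                )
            )
    return reports


def dedupe(
    profiles: Sequence[DNAProfile],
    reports: Sequence[DuplicateReport],
    scope: str = "location",
) -> list[DNAProfile]:
    """Retain one copy of each unique genotype per stratum.

    Duplicate pairs are clustered (transitively) within each ``scope`` stratum
    (location | habitat | management_unit); the member with the most typed
    loci is kept, ties broken by lexicographic sample id.  Pairs spanning two
    different strata are both retained — the per-stratum rule.  Idempotent.
    """
    by_id = {p.sample_id: p for p in profiles}
    key = {
        "location": lambda p: p.location,
        "habitat": lambda p: p.habitat,
        "management_unit": lambda p: p.management_unit,
    }[scope]

    # union-find over same-stratum duplicate pairs
    parent = {sid: sid for sid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rep in reports:
        a, b = rep.pair
        if a in by_id and b in by_id and key(by_id[a]) == key(by_id[b]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    clusters: dict[str, list[DNAProfile]] = {}
    for sid, p in by_id.items():
        clusters.setdefault(find(sid), []).append(p)
    keep = set()
    for members in clusters.values():
        best = min(members, key=lambda p: (-len(p.genotype), p.sample_id))
        keep.add(best.sample_id)
    return [p for p in profiles if p.sample_id in keep]


def _genotype_log_prob(table: Mapping[tuple[int, int], int]) -> float:
    """Log conditional probability (up to a constant in the allele counts) of a
    genotype table given its allele counts under HWE: ∝ 2^H / Π n_ij!"""
    het = sum(c for (a, b), c in table.items() if a != b)
    return het * np.log(2.0) - float(
        sum(gammaln(c + 1.0) for c in table.values())
    )


def hwe_exact_test(
    genotype_counts: Mapping[tuple[int, int], int],
    n_steps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test of Hardy–Weinberg equilibrium at one locus.

    ``genotype_counts`` maps unordered allele pairs to counts.  Gene copies
    are pooled and randomly re-paired ``n_steps`` times — an exact draw from
    the null distribution of genotype tables conditional on the allele counts.
    The p-value is the (add-one smoothed) fraction of tables at most as
    probable as the observed one.

    Monomorphic locus: p = 1 with a warning.
    """
    table = {}
    for (a, b), c in genotype_counts.items():
        if c < 0:
            raise ValueError("genotype counts must be >= 0")
        if c:
            key = (a, b) if a <= b else (b, a)
            table[key] = table.get(key, 0) + c
    copies: list[int] = []
    for (a, b), c in table.items():
        copies += [a, b] * c
    alleles = sorted(set(copies))
    if len(alleles) < 2:
        warnings.warn("monomorphic locus: HWE test undefined, p = 1")
        return 1.0

    idx = {al: i for i, al in enumerate(alleles)}
    k = len(alleles)
    copies_arr = np.array([idx[a] for a in copies], dtype=np.int64)
    n2 = copies_arr.size  # 2n gene copies

    obs_lp = _genotype_log_prob(table)

    rng = np.random.default_rng(seed)
    # batched random re-pairings of the gene copies
    count_at_most = 0
    batch = 2000
    done = 0
    log2 = np.log(2.0)
    while done < n_steps:
        b = min(batch, n_steps - done)
        perms = np.argsort(rng.random((b, n2)), axis=1)
        shuffled = copies_arr[perms].reshape(b, n2 // 2, 2)
        lo = shuffled.min(axis=2)
        hi = shuffled.max(axis=2)
        codes = lo * k + hi  # unordered-pair code
        # per-row genotype tables via offset bincount
        flat = (codes + (np.arange(b)[:, None] * k * k)).ravel()
        counts = np.bincount(flat, minlength=b * k * k).reshape(b, k * k)
        het_mask = (np.arange(k * k) // k) != (np.arange(k * k) % k)
        lps = (counts[:, het_mask].sum(axis=1)) * log2 - gammaln(counts + 1.0).sum(axis=1)
        count_at_most += int((lps <= obs_lp + 1e-12).sum())
        done += b
    return (count_at_most + 1) / (n_steps + 1)
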