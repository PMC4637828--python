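"""Factorial correspondence analysis of multi-locus genotypes.

Individuals are encoded as allele-count vectors (0/1/2 copies of each allele,
the Genetix convention) and ordinated by correspondence analysis — a
chi-square-metric SVD of the centred row-profile matrix.  Used to visualise
overlap between calving grounds and migratory corridors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import DNAProfile, locus_union


@dataclass(frozen=True)
class FCAResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # individuals × leading axes, principal coordinates
    inertias: np.ndarray  # eigenvalue per axis (all nonzero axes), non-increasing
    percent_inertia: np.ndarray  # of total inertia, sums to 100 over all axes

    @property
    def total_inertia(self) -> float:
        return float(self.inertias.sum())


def allele_indicator_matrix(
    profiles: Sequence[DNAProfile],
) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    """Individuals × alleles matrix of allele copy counts.

    Entry (i, (locus, allele)) is 0, 1 or 2 — how many copies individual i
    carries.  Missing loci contribute zeros (their mass is simply absent from
    the row).  Returns (matrix, sample ids, column keys).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile set")
    loci = locus_union(profiles)
    columns: list[tuple[str, int]] = []
    for locus in loci:
        alleles = sorted({a for p in profiles if locus in p.genotype for a in p.genotype[locus]})
        columns += [(locus, a) for a in alleles]
    col_index = {key: j for j, key in enumerate(columns)}
    X = np.zeros((len(profiles), len(columns)))
    for i, p in enumerate(profiles):
        for locus, (a, b) in p.genotype.items():
            X[i, col_index[(locus, a)]] += 1
            X[i, col_index[(locus, b)]] += 1
    return X, [p.sample_id for p in profiles], columns


def fca_coordinates(
    matrix: np.ndarray,
    n_axes: int = 2,
    sample_ids: Sequence[str] | None = None,
) -> FCAResult:
    """Correspondence analysis of a nonnegative count matrix.

    Row principal coordinates of the chi-square-metric decomposition: with
    correspondence matrix P = X/ΣX, row masses r, column masses c, the SVD of
    ``D_r^(-1/2) (P − r cᵀ) D_c^(-1/2)`` gives axis inertias (squared singular
    values, summing to the table's total inertia = χ²/ΣX) and row coordinates
    ``D_r^(-1/2) U Σ``.  Deterministic up to sign; the sign of each axis is
    fixed by making its largest-|coordinate| entry positive.  Rank-deficient
    tables return fewer axes than requested.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or np.any(X < 0):
        raise ValueError("matrix must be a nonnegative 2-D array")
    total = X.sum()
    if total == 0:
        raise ValueError("matrix has zero total")
    keep_rows = X.sum(axis=1) > 0
    keep_cols = X.sum(axis=0) > 0
    if not keep_rows.all():
        raise ValueError("rows with zero mass (individuals typed at no locus)")
    Xr = X[:, keep_cols]

    P = Xr / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    nz = sv > tol
    U, sv = U[:, nz], sv[nz]
    inertias = sv**2
    total_inertia = float(inertias.sum())

    k = min(n_axes, sv.size)
    coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    pct = 100.0 * inertias / total_inertia if total_inertia > 0 else np.zeros_like(inertias)
    ids = tuple(sample_ids) if sample_ids is not None else tuple(str(i) for i in range(X.shape[0]))
    return FCAResult(
        sample_ids=ids,
        coordinates=coords,
        inertias=inertias,
        percent_inertia=pct,
    )


def fca_of_profiles(profiles: Sequence[DNAProfile], n_axes: int = 2) -> FCAResult:
    """Convenience wrapper: indicator matrix + CA in one step."""
    X, ids, _ = allele_indicator_matrix(profiles)
    return fca_coordinates(X, n_axes=n_axes, sample_ids=ids)
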