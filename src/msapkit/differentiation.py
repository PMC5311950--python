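"""Population differentiation on dominant binary markers.

The substrate is the matrix of pairwise squared Euclidean distances
between individual band/state vectors (mismatch counts, rescaled for
pairwise-complete comparison under missing data).  AMOVA decomposes the
total molecular variance into among- and within-population components;
PhiST = sigma2_among / (sigma2_among + sigma2_within) is the
dominant-marker analogue of FST, with significance from a permutation
test shuffling individuals among populations.  PCoA (metric MDS via Gower
double-centering) provides the ordination view of the same distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BandMatrixPair, EmptyAnalysisError, MsapError
from .scoring import polymorphism_filter


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise squared distances between individuals."""

    ids: list[str]
    values: np.ndarray  # squared distances
    metric: str = "sq_euclidean"
    missing_policy: str = "pairwise"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MsapError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise MsapError("distance matrix must be symmetric")
        if np.diag(self.values).any():
            raise MsapError("distance matrix must have a zero diagonal")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise MsapError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, mask: np.ndarray) -> "DistanceMatrix":
        idx = np.flatnonzero(mask)
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            metric=self.metric,
            missing_policy=self.missing_policy,
        )


@dataclass
class AMOVAResult:
    """Among/within variance components, PhiST and its permutation test."""

    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    n0: float
    method: str = "permutation"

    @property
    def percent_among(self) -> float:
        total = self.sigma2_among + self.sigma2_within
        return 100.0 * self.sigma2_among / total if total else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations"],
                "df": [self.df_among, self.df_within],
                "ss": [self.ss_among, self.ss_within],
                "variance_component": [self.sigma2_among, self.sigma2_within],
                "percent": [self.percent_among, 100.0 - self.percent_among],
            }
        )


@dataclass
class PCoAResult:
    """Principal-coordinates ordination of a squared-distance matrix."""

    ids: list[str]
    coordinates: np.ndarray          # individuals x positive axes
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    percent_variance: np.ndarray     # over the positive spectrum
    negative_eigenvalues: np.ndarray # reported, never silently dropped

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis_{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "individual", self.ids)
        return df


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def pairwise_distance(
    matrix: np.ndarray,
    ids: list[str] | None = None,
    metric: str = "sq_euclidean",
    missing_policy: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise squared Euclidean distances on a binary matrix with missing.

    For binary vectors the squared Euclidean distance is the mismatch
    count.  Under the default ``pairwise`` policy each pair is compared
    over its pairwise-complete loci and the mismatch count is rescaled by
    L / (#compared loci); under ``complete`` loci with any missing entry
    are dropped once for all pairs.  A pair with zero shared non-missing
    loci is an error naming the pair.
    """
    if metric != "sq_euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if missing_policy not in ("pairwise", "complete"):
        raise ValueError(f"unsupported missing policy {missing_policy!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise EmptyAnalysisError("pairwise_distance needs >= 2 individuals")
    ids = list(ids) if ids is not None else [f"ind{i}" for i in range(m.shape[0])]
    n, L = m.shape
    if missing_policy == "complete":
        complete = ~np.isnan(m).any(axis=0)
        if not complete.any():
            raise EmptyAnalysisError("no complete loci under complete-case policy")
        m = m[:, complete]
        L = m.shape[1]

    valid = ~np.isnan(m)
    filled = np.nan_to_num(m)
    # mismatches over pairwise-complete loci, vectorized over all pairs
    both = valid.astype(float) @ valid.astype(float).T            # compared loci
    same_ones = filled @ filled.T
    ones_vs_valid = filled @ valid.astype(float).T                # x_i=1 and j observed
    mism = (ones_vs_valid - same_ones) + (ones_vs_valid.T - same_ones)
    if (both + np.eye(n) * 1 == 0).any():
        i, j = np.argwhere((both == 0) & ~np.eye(n, dtype=bool))[0]
        raise MsapError(f"individuals {ids[i]!r} and {ids[j]!r} share no scored loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(both > 0, mism * (L / np.maximum(both, 1)), 0.0)
    np.fill_diagonal(d2, 0.0)
    d2 = (d2 + d2.T) / 2
    return DistanceMatrix(ids=ids, values=d2, metric=metric, missing_policy=missing_policy)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _amova_components(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, ...]:
    """Sums of squares and variance components for one labelling.

    SS_total = sum_{i<j} d2_ij / N; SS_within = sum over groups of the
    within-group pairwise sums / n_g; sigma2_w = SS_w / (N-K) and
    sigma2_a = (MS_a - sigma2_w) / n0 with n0 = (N - sum n_g^2 / N)/(K-1).
    """
    n = d2.shape[0]
    total = d2.sum() / 2.0
    ss_total = total / n
    ss_within = 0.0
    sizes = np.zeros(n_groups)
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        sizes[g] = n_g
        ss_within += d2[np.ix_(mask, mask)].sum() / 2.0 / n_g
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_w = ss_within / df_within
    sigma2_a = (ss_among / df_among - sigma2_w) / n0
    return ss_among, ss_within, sigma2_a, sigma2_w, n0


def _phi(sigma2_a: float, sigma2_w: float) -> float:
    total = sigma2_a + sigma2_w
    return sigma2_a / total if total != 0 else 0.0


def _count_assignments(sizes: list[int]) -> int:
    n = sum(sizes)
    count = 1
    for s in sizes:
        count *= math.comb(n, s)
        n -= s
    return count


def amova(
    dist: DistanceMatrix,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> AMOVAResult:
    """Distance-based AMOVA with a PhiST permutation test.

    Individuals are permuted among populations with group sizes fixed;
    the Monte Carlo p-value uses the +1/+1 convention (observed
    arrangement included), so p > 0 always.  ``method="exact"``
    enumerates every distinct assignment of individuals to groups
    instead, yielding the exact permutation p (the observed arrangement
    counts once).  Negative PhiST estimates are reported as computed.
    """
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != dist.n:
        raise MsapError("group labels do not match distance matrix")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise MsapError("AMOVA needs >= 2 populations")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(labels[g]) for g in np.flatnonzero(sizes < 2)]
        raise MsapError(f"singleton populations not allowed in AMOVA: {small}")
    if method == "permutation" and n_perm < 1:
        raise MsapError("n_perm must be >= 1")

    d2 = dist.values
    ss_a, ss_w, s2a, s2w, n0 = _amova_components(d2, codes, k)
    phi_obs = _phi(s2a, s2w)

    if method == "exact":
        hits = 0
        total = 0
        for perm_codes in _distinct_assignments(codes):
            _, _, pa, pw, _ = _amova_components(d2, perm_codes, k)
            total += 1
            if _phi(pa, pw) >= phi_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm_codes = rng.permutation(codes)
            _, _, pa, pw, _ = _amova_components(d2, perm_codes, k)
            if _phi(pa, pw) >= phi_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        n_used = n_perm

    return AMOVAResult(
        sigma2_among=s2a,
        sigma2_within=s2w,
        phi_st=phi_obs,
        p_value=p,
        n_permutations=n_used,
        seed=seed,
        ss_among=ss_a,
        ss_within=ss_w,
        df_among=k - 1,
        df_within=dist.n - k,
        n0=n0,
        method=method,
    )


def _distinct_assignments(codes: np.ndarray):
    """Yield every distinct assignment of individuals to the group sizes."""
    n = codes.shape[0]
    k = codes.max() + 1
    sizes = np.bincount(codes, minlength=k)

    def rec(remaining: tuple[int, ...], g: int, out: np.ndarray):
        if g == k - 1:
            final = out.copy()
            final[list(remaining)] = g
            yield final
            return
        for chosen in itertools.combinations(remaining, int(sizes[g])):
            nxt = out.copy()
            nxt[list(chosen)] = g
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, g + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.full(n, -1, dtype=int))


def n_distinct_assignments(groups: np.ndarray) -> int:
    """Number of distinct assignments of individuals to the observed group sizes."""
    _, codes = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    return _count_assignments(list(np.bincount(codes)))


def pairwise_phist(
    matrix: np.ndarray,
    ids: list[str],
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    missing_policy: str = "pairwise",
) -> pd.DataFrame:
    """Pairwise PhiST and permutation p for every population pair.

    Each pair of populations is subset from the binary matrix, distances
    recomputed on the subset, and the two-group AMOVA applied.  Returns a
    long-form DataFrame (pop_a, pop_b, phi_st, p_value, n_a, n_b); use
    :func:`phist_matrix` for the square layout.  Per-pair permutation
    streams are derived deterministically from ``seed``.
    """
    groups = np.asarray(groups, dtype=object)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise MsapError("pairwise PhiST needs >= 2 populations")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        mask = (groups == a) | (groups == b)
        sub = np.asarray(matrix, dtype=float)[mask]
        sub_ids = [i for i, m in zip(ids, mask) if m]
        sub_groups = groups[mask]
        dist = pairwise_distance(sub, ids=sub_ids, missing_policy=missing_policy)
        pair_seed = None
        if seed is not None:
            ss = np.random.SeedSequence(seed, spawn_key=(labels.index(a), labels.index(b)))
            pair_seed = int(ss.generate_state(1)[0] % (2**31))
        res = amova(dist, sub_groups, n_perm=n_perm, seed=pair_seed)
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "phi_st": res.phi_st,
                "p_value": res.p_value,
                "n_a": int((groups == a).sum()),
                "n_b": int((groups == b).sum()),
            }
        )
    return pd.DataFrame(rows)


def phist_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric PhiST matrix from the long-form pairwise table."""
    labels = list(pd.unique(table[["pop_a", "pop_b"]].to_numpy().ravel()))
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for _, row in table.iterrows():
        out.loc[row["pop_a"], row["pop_b"]] = row["phi_st"]
        out.loc[row["pop_b"], row["pop_a"]] = row["phi_st"]
    np.fill_diagonal(out.values, 0.0)
    return out


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Principal coordinates of a squared-distance matrix.

    Gower double-centering of -1/2 D2, eigendecomposition, coordinates on
    positive-eigenvalue axes scaled by sqrt(eigenvalue).  Percent
    variance is over the positive spectrum; negative eigenvalues (from
    non-Euclidean distances after missing-data rescaling) are reported.
    """
    d2 = dist.values
    if not d2.any():
        raise EmptyAnalysisError("all distances are zero; PCoA is degenerate")
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1])) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    percent = 100.0 * eigvals[pos] / eigvals[pos].sum()
    return PCoAResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=eigvals[pos],
        percent_variance=percent,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


# ---------------------------------------------------------------------------
# AFLP mode
# ---------------------------------------------------------------------------


def aflp_mode_phist(
    pair: BandMatrixPair,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[AMOVAResult, pd.DataFrame]:
    """Genetic differentiation treating both digests as plain AFLP.

    The HPA and MSP profiles of each individual are concatenated into one
    presence/absence fingerprint over 2L columns; the polymorphism filter
    (>=2 of each state) is applied per column; global AMOVA and the
    pairwise PhiST table are computed on the result — an all-loci second
    measure of genetic differentiation alongside NML.
    """
    concat = np.hstack([pair.hpa, pair.msp]).astype(float)
    keep = polymorphism_filter(concat)
    if not keep.any():
        raise EmptyAnalysisError("no polymorphic columns in AFLP-mode fingerprint")
    mat = concat[:, keep]
    dist = pairwise_distance(mat, ids=list(pair.individuals))
    global_res = amova(dist, groups, n_perm=n_perm, seed=seed)
    table = pairwise_phist(mat, list(pair.individuals), groups, n_perm=n_perm, seed=seed)
    return global_res, table
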