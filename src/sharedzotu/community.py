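"""Presence/absence community comparison between host species.

Dissimilarity between two individuals is the Sørensen form of Bray–Curtis on
presence/absence: d = (A + B - 2J)/(A + B), with A and B the ZOTU richness of
each individual and J the number of shared ZOTUs. Community structure is
tested with PERMANOVA on the dissimilarity matrix, preceded by a test of
multivariate homogeneity of group dispersions (distance to group centroid in
principal-coordinates space, keeping negative-eigenvalue axes as an imaginary
part). Core-ZOTU ranking and class-level composition summarize the
read-abundance side of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import OccurrenceMatrix, RRAMatrix


@dataclass
class DissimilarityMatrix:
    """Pairwise Sørensen dissimilarities with A, B, J accessible per pair."""

    ids: list
    values: np.ndarray       # symmetric, zero diagonal, entries in [0, 1]
    richness: np.ndarray     # A_i: per-individual ZOTU richness
    shared: np.ndarray       # J_ij: shared ZOTU counts

    def pair(self, i, j):
        """(A, B, J, d) for a pair of individual ids."""
        a = self.ids.index(i)
        b = self.ids.index(j)
        return (int(self.richness[a]), int(self.richness[b]),
                int(self.shared[a, b]), float(self.values[a, b]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def sorensen(matrix: OccurrenceMatrix) -> DissimilarityMatrix:
    """Sørensen (presence/absence Bray–Curtis) dissimilarity between
    individuals: (A + B - 2J)/(A + B)."""
    pres = matrix.presence.to_numpy().astype(np.int64)
    if pres.shape[1] < 2:
        raise ValueError("need at least 2 individuals")
    shared = pres.T @ pres                     # J
    richness = pres.sum(axis=0)                # A
    denom = richness[:, None] + richness[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (denom - 2 * shared) / denom
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids=list(matrix.presence.columns), values=d,
                               richness=richness, shared=shared)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    n_groups: int
    n_samples: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova(dist: DissimilarityMatrix, groups, n_perm: int = 10000,
              seed=None) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    SS_total = sum of squared dissimilarities / N; SS_within sums the
    per-group analogues; pseudo-F = (SS_among/(g-1)) / (SS_within/(N-g));
    p is permutational with the add-one convention.
    """
    labels = pd.Series(list(groups), index=dist.ids)
    codes, uniq = pd.factorize(labels)
    n = len(codes)
    g = len(uniq)
    counts = np.bincount(codes)
    if g == 1:
        return PermanovaResult(float("nan"), 0.0, float("nan"), 0, 1, n)
    if counts.min() < 2:
        small = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    d2 = dist.values.astype(float) ** 2
    ss_total = d2.sum() / (2 * n)

    def pseudo_f(code_vec):
        ssw = _ss_within(d2, code_vec, g)
        ssa = ss_total - ssw
        if ssw == 0:
            return float("inf"), ssa
        return (ssa / (g - 1)) / (ssw / (n - g)), ssa

    f_obs, ss_among = pseudo_f(codes)
    r2 = 1.0 if ss_total == 0 else ss_among / ss_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(codes))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=float(p),
                           n_perm=n_perm, n_groups=g, n_samples=n)


@dataclass
class DispersionResult:
    f: float
    df1: int
    df2: int
    p: float
    group_means: dict
    distances: pd.Series


def pcoa_embedding(d: np.ndarray, tol: float = 1e-10):
    """Principal coordinates of a distance matrix.

    Returns (real_axes, imaginary_axes): coordinates on positive- and
    negative-eigenvalue axes; squared distances in the original space equal
    squared real distances minus squared imaginary distances.
    """
    n = d.shape[0]
    a = -0.5 * d.astype(float) ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((gower + gower.T) / 2)
    scale = np.abs(eigval).max() if eigval.size else 1.0
    cut = tol * max(scale, 1.0)
    pos = eigval > cut
    neg = eigval < -cut
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def dispersion_test(dist: DissimilarityMatrix, groups,
                    centroid: str = "centroid") -> DispersionResult:
    """Homogeneity of multivariate group dispersions.

    Each individual's distance to its group centroid is computed in PCoA
    space as sqrt(real-part squared distance - imaginary-part squared
    distance), negative values clamped to zero; a one-way ANOVA F with
    (g-1, N-g) df tests equality of mean dispersions across groups.

    Only the group mean (``centroid="centroid"``) is supported as the centre;
    it is the deterministic choice.
    """
    if centroid != "centroid":
        raise NotImplementedError(
            "only the group-mean centroid is implemented; the spatial-median "
            "variant of the reference software is not"
        )
    labels = pd.Series(list(groups), index=dist.ids)
    codes, uniq = pd.factorize(labels)
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    real, imag = pcoa_embedding(dist.values)
    n = len(codes)
    g = len(uniq)
    dist_to_centroid = np.empty(n)
    for gi in range(g):
        idx = np.flatnonzero(codes == gi)
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        sq = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            sq = sq - ((imag[idx] - ci) ** 2).sum(axis=1)
        neg = sq < 0
        if neg.any():
            import logging
            logging.getLogger("sharedzotu").warning(
                "dispersion_test: clamping %d negative squared distance(s)",
                int(neg.sum()))
            sq = np.clip(sq, 0, None)
        dist_to_centroid[idx] = np.sqrt(sq)
    per_group = [dist_to_centroid[codes == gi] for gi in range(g)]
    f, p = stats.f_oneway(*per_group)
    return DispersionResult(
        f=float(f), df1=g - 1, df2=n - g, p=float(p),
        group_means={str(uniq[gi]): float(per_group[gi].mean()) for gi in range(g)},
        distances=pd.Series(dist_to_centroid, index=dist.ids),
    )


def core_zotus(rra: RRAMatrix, occurrence: OccurrenceMatrix, k: int = 50) -> list:
    """The k most-core ZOTUs: ranked by overall prevalence (fraction of all
    individuals occupied), ties broken by total RRA descending, then id."""
    pres = occurrence.presence
    if k > len(pres.index):
        raise ValueError(f"k={k} exceeds the {len(pres.index)} available ZOTUs")
    prevalence = pres.mean(axis=1)
    total_rra = rra.values.reindex(index=pres.index,
                                   columns=pres.columns).fillna(0).sum(axis=1)
    order = pd.DataFrame({"prev": prevalence, "rra": total_rra})
    order = order.sort_values(["prev", "rra"],
                              ascending=[False, False], kind="mergesort")
    # stable sort on id first, then keys, gives the lexical tie-break
    order = order.loc[sorted(order.index)].sort_values(
        ["prev", "rra"], ascending=[False, False], kind="mergesort")
    return list(order.index[:k])


def class_composition(rra: RRAMatrix, taxonomy: pd.DataFrame,
                      partition: pd.Series) -> pd.DataFrame:
    """Mean per-species RRA share (%) of each bacterial class.

    Per individual, RRA sums by assigned class (unassigned pooled as
    "unclassified"); shares are then averaged over each species' individuals
    and reported in percent. Rows are species, columns classes; each row sums
    to 100.
    """
    klass = taxonomy["class"].reindex(rra.values.index).fillna("")
    klass = klass.where(klass != "", "unclassified")
    by_class = rra.values.groupby(klass, sort=False).sum()  # class x individual
    per_species = by_class.T.groupby(partition.reindex(by_class.columns),
                                     sort=False).mean()
    return per_species * 100.0
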