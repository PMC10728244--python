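"""Fixed-fixed null models of ZOTU sharedness across host species.

The question: are ZOTUs more (or less) host-species-specific than expected by
chance, once each ZOTU's overall rarity and each individual's observed ZOTU
load are taken as given? The null holds both margins of the binary
ZOTU x individual matrix fixed — every randomized matrix has exactly the
observed row sums (per-ZOTU incidence) and column sums (per-individual
richness) — and asks how the counts of ZOTUs spanning k host species, and of
ZOTUs occupying each particular species combination (Venn cell), distribute
under random placement.

Two samplers are provided:

* ``quasiswap`` (default) — each draw is independent: an integer matrix with
  the target margins is built by random allocation, then random 2x2 moves
  that never increase the sum of squared entries are applied until the
  matrix is binary, followed by a burn-in of neutral checkerboard swaps.
  Stopping at the first binary matrix (as the classical quasi-swap does)
  leaves a measurable bias on some margins; the checkerboard-swap chain is
  symmetric and connected over the fixed-margin binary matrices, so the
  extra mixing phase restores uniformity.
* ``curveball`` — a Markov chain started at the observed matrix, advanced by
  random "trades" of species between pairs of individuals; a burn-in of
  ``5 * max(n_rows, n_cols) * ln(n_rows)`` trades is applied per draw.

Interval summaries use the 95% highest density continuous interval (HDCI):
the shortest contiguous window of the sorted null sample containing at least
``ceil(mass * n)`` draws, ties broken toward the smaller lower endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import OccurrenceMatrix, ValidationError


# ---------------------------------------------------------------------------
# samplers (numba kernels)


@njit(cache=True)
def _quasiswap_kernel(row_sums, col_sums, seed, n_mix):
    """Sample a binary matrix with the given margins.

    Random fill: pair a shuffled multiset of column labels with the row
    multiset. Then 2x2 moves that never increase the sum of squares, each
    anchored at a randomly chosen overfull cell, until no entry exceeds 1;
    finally ``n_mix`` uniformly-proposed attempts in which only neutral
    checkerboard swaps can fire (the symmetric, connected chain whose
    stationary distribution is uniform over the fixed-margin matrices).
    """
    np.random.seed(seed)
    nr = row_sums.shape[0]
    nc = col_sums.shape[0]
    total = 0
    for i in range(nr):
        total += row_sums[i]
    pool = np.empty(total, np.int64)
    k = 0
    for j in range(nc):
        for _ in range(col_sums[j]):
            pool[k] = j
            k += 1
    for i in range(total - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = pool[i]
        pool[i] = pool[j]
        pool[j] = tmp
    m = np.zeros((nr, nc), np.int64)
    k = 0
    for i in range(nr):
        for _ in range(row_sums[i]):
            m[i, pool[k]] += 1
            k += 1
    if nr < 2 or nc < 2:
        return m  # no 2x2 moves possible; margins force the matrix

    # registry of overfull cells (entries > 1), with O(1) add/remove
    over_i = np.empty(nr * nc, np.int64)
    over_j = np.empty(nr * nc, np.int64)
    slot = np.full((nr, nc), -1, np.int64)
    n_over = 0
    for i in range(nr):
        for j in range(nc):
            if m[i, j] > 1:
                over_i[n_over] = i
                over_j[n_over] = j
                slot[i, j] = n_over
                n_over += 1

    while n_over > 0:
        k = np.random.randint(0, n_over)
        i1 = over_i[k]
        j1 = over_j[k]
        i2 = np.random.randint(0, nr - 1)
        if i2 >= i1:
            i2 += 1
        j2 = np.random.randint(0, nc - 1)
        if j2 >= j1:
            j2 += 1
        a = m[i1, j1]
        b = m[i1, j2]
        c = m[i2, j1]
        d = m[i2, j2]
        if d > 0 and a + d >= b + c + 2:
            m[i1, j1] = a - 1
            m[i2, j2] = d - 1
            m[i1, j2] = b + 1
            m[i2, j1] = c + 1
            # update registry for the four cells
            if a - 1 <= 1 and slot[i1, j1] >= 0:
                s = slot[i1, j1]
                n_over -= 1
                over_i[s] = over_i[n_over]
                over_j[s] = over_j[n_over]
                slot[over_i[s], over_j[s]] = s
                slot[i1, j1] = -1
            if d - 1 <= 1 and slot[i2, j2] >= 0:
                s = slot[i2, j2]
                n_over -= 1
                over_i[s] = over_i[n_over]
                over_j[s] = over_j[n_over]
                slot[over_i[s], over_j[s]] = s
                slot[i2, j2] = -1
            if b + 1 > 1 and slot[i1, j2] < 0:
                over_i[n_over] = i1
                over_j[n_over] = j2
                slot[i1, j2] = n_over
                n_over += 1
            if c + 1 > 1 and slot[i2, j1] < 0:
                over_i[n_over] = i2
                over_j[n_over] = j1
                slot[i2, j1] = n_over
                n_over += 1

    for _ in range(n_mix):
        i1 = np.random.randint(0, nr)
        i2 = np.random.randint(0, nr - 1)
        if i2 >= i1:
            i2 += 1
        j1 = np.random.randint(0, nc)
        j2 = np.random.randint(0, nc - 1)
        if j2 >= j1:
            j2 += 1
        a = m[i1, j1]
        b = m[i1, j2]
        c = m[i2, j1]
        d = m[i2, j2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            m[i1, j1] = 0
            m[i2, j2] = 0
            m[i1, j2] = 1
            m[i2, j1] = 1
        elif b == 1 and c == 1 and a == 0 and d == 0:
            m[i1, j2] = 0
            m[i2, j1] = 0
            m[i1, j1] = 1
            m[i2, j2] = 1
    return m


@njit(cache=True)
def _curveball_kernel(m, n_trades, seed):
    """Advance a binary matrix by curveball trades in place."""
    np.random.seed(seed)
    nr, nc = m.shape
    only1 = np.empty(nc, np.int64)
    only2 = np.empty(nc, np.int64)
    pool = np.empty(nc, np.int64)
    for _ in range(n_trades):
        i1 = np.random.randint(0, nr)
        i2 = np.random.randint(0, nr - 1)
        if i2 >= i1:
            i2 += 1
        n1 = 0
        n2 = 0
        for j in range(nc):
            if m[i1, j] == 1 and m[i2, j] == 0:
                only1[n1] = j
                n1 += 1
            elif m[i1, j] == 0 and m[i2, j] == 1:
                only2[n2] = j
                n2 += 1
        if n1 == 0 or n2 == 0:
            continue
        nu = n1 + n2
        for k in range(n1):
            pool[k] = only1[k]
        for k in range(n2):
            pool[n1 + k] = only2[k]
        for i in range(nu - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
        for k in range(nu):
            j = pool[k]
            if k < n1:
                m[i1, j] = 1
                m[i2, j] = 0
            else:
                m[i1, j] = 0
                m[i2, j] = 1
    return m


def _check_binary(arr: np.ndarray) -> None:
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValidationError("null model input must be a binary matrix")


def sample_fixed_fixed(arr: np.ndarray, seed: int, method: str = "quasiswap") -> np.ndarray:
    """One randomized binary matrix with the margins of ``arr`` (ndarray API)."""
    _check_binary(arr)
    arr = np.ascontiguousarray(arr, dtype=np.int64)
    seed = int(seed) % (2 ** 31)
    if method == "quasiswap":
        r = arr.sum(axis=1).astype(np.int64)
        c = arr.sum(axis=0).astype(np.int64)
        n_mix = max(200, 10 * int(r.sum()))
        return _quasiswap_kernel(r, c, seed, n_mix)
    if method == "curveball":
        nr, nc = arr.shape
        burn = int(math.ceil(5 * max(nr, nc) * math.log(max(nr, 2))))
        return _curveball_kernel(arr.copy(), burn, seed)
    raise ValueError(f"unknown null-model method {method!r}")


def quasi_swap(matrix: OccurrenceMatrix, seed=None, method: str = "quasiswap") -> OccurrenceMatrix:
    """An independently sampled occurrence matrix with the observed margins."""
    seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31)
    arr = sample_fixed_fixed(matrix.presence.to_numpy(), seed, method=method)
    presence = matrix.presence.copy()
    presence.loc[:, :] = arr.astype(np.int8)
    return OccurrenceMatrix(presence, matrix.partition.copy())


# ---------------------------------------------------------------------------
# sharedness statistics


@dataclass
class SharednessProfile:
    """Counts of ZOTUs per number-of-species and per species combination."""

    species: list
    span_counts: np.ndarray          # index k-1 -> # ZOTUs in exactly k species
    venn_counts: dict                # tuple(species subset) -> count

    @property
    def total(self) -> int:
        return int(self.span_counts.sum())

    def as_records(self) -> dict:
        out = {f"span_{k + 1}": int(v) for k, v in enumerate(self.span_counts)}
        out.update({"venn_" + "+".join(key): int(v)
                    for key, v in self.venn_counts.items()})
        return out


def _species_codes(matrix: OccurrenceMatrix):
    species = matrix.species
    lookup = {s: i for i, s in enumerate(species)}
    codes = np.array([lookup[matrix.partition[c]] for c in matrix.presence.columns])
    return species, codes


def _profile_from_array(arr: np.ndarray, codes: np.ndarray, species: list) -> SharednessProfile:
    n_sp = len(species)
    bitmask = np.zeros(arr.shape[0], dtype=np.int64)
    span = np.zeros(arr.shape[0], dtype=np.int64)
    for s in range(n_sp):
        hit = arr[:, codes == s].any(axis=1)
        bitmask |= hit.astype(np.int64) << s
        span += hit
    span_counts = np.bincount(span, minlength=n_sp + 1)[1:n_sp + 1]
    venn_raw = np.bincount(bitmask, minlength=2 ** n_sp)
    venn = {}
    for mask in range(1, 2 ** n_sp):
        subset = tuple(species[s] for s in range(n_sp) if mask >> s & 1)
        venn[subset] = int(venn_raw[mask])
    return SharednessProfile(species=species, span_counts=span_counts, venn_counts=venn)


def sharedness(matrix: OccurrenceMatrix) -> SharednessProfile:
    """Observed sharedness profile: span counts and Venn-cell counts."""
    species, codes = _species_codes(matrix)
    return _profile_from_array(matrix.presence.to_numpy().astype(bool), codes, species)


# ---------------------------------------------------------------------------
# interval + ensemble summary


def hdci(values, mass: float = 0.95):
    """Highest density continuous interval of an empirical sample.

    Shortest window of the sorted values containing at least
    ``ceil(mass * n)`` points; ties in width resolve to the smallest lower
    endpoint.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("hdci of an empty sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    m = min(max(int(math.ceil(mass * n)), 1), n)
    widths = v[m - 1:] - v[:n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(v[i]), float(v[i + m - 1])


@dataclass
class NullEnsembleSummary:
    """Observed vs null summaries for every sharedness statistic."""

    statistics: dict                 # name -> record dict
    n_rand: int
    mass: float
    seed: object
    method: str

    def exceedances(self) -> dict:
        return {k: rec["exceeds"] for k, rec in self.statistics.items()}

    def to_dict(self) -> dict:
        return {
            "n_rand": self.n_rand, "mass": self.mass,
            "seed": self.seed, "method": self.method,
            "statistics": self.statistics,
        }


def null_compare(matrix: OccurrenceMatrix, n_rand: int = 1000,
                 mass: float = 0.95, seed=None,
                 method: str = "quasiswap") -> NullEnsembleSummary:
    """Randomize the matrix ``n_rand`` times and summarize each sharedness
    statistic (span counts, span proportions, Venn-cell counts) with its null
    mean, SD, 95% HDCI, and an exceedance flag (observed outside the HDCI)."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    species, codes = _species_codes(matrix)
    arr = matrix.presence.to_numpy().astype(np.int64)
    _check_binary(arr)
    observed = _profile_from_array(arr.astype(bool), codes, species)
    total = observed.total
    obs_records = observed.as_records()

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_rand, dtype=np.uint32) % (2 ** 31)
    names = list(obs_records)
    draws = np.empty((n_rand, len(names)), dtype=np.int64)
    for b in range(n_rand):
        null_arr = sample_fixed_fixed(arr, int(child_seeds[b]), method=method)
        rec = _profile_from_array(null_arr.astype(bool), codes, species).as_records()
        draws[b] = [rec[name] for name in names]

    statistics = {}
    for j, name in enumerate(names):
        col = draws[:, j].astype(float)
        lo, hi = hdci(col, mass=mass)
        obs = float(obs_records[name])
        statistics[name] = {
            "observed": obs,
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if n_rand > 1 else 0.0,
            "lower": lo,
            "upper": hi,
            "exceeds": bool(obs < lo or obs > hi),
            "n_rand": n_rand,
        }
    # span proportions: same exceedance as counts (the total is fixed), but
    # reported on the scale used for plotting
    for k in range(len(species)):
        cname = f"span_{k + 1}"
        rec = statistics[cname]
        statistics[f"prop_{k + 1}"] = {
            "observed": rec["observed"] / total,
            "mean": rec["mean"] / total,
            "sd": rec["sd"] / total,
            "lower": rec["lower"] / total,
            "upper": rec["upper"] / total,
            "exceeds": rec["exceeds"],
            "n_rand": n_rand,
        }
    return NullEnsembleSummary(statistics=statistics, n_rand=n_rand,
                               mass=mass, seed=seed, method=method)
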