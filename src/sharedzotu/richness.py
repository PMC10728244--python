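"""Per-host-species richness analytics on the occurrence matrix.

Covers observed ZOTU richness, sample-based accumulation curves, extrapolated
total richness (bias-corrected Chao2 and first-order jackknife, both
incidence-based, with standard errors), the unique/shared partition of ZOTUs
by host-species span, and per-ZOTU mean incidence with BCa bootstrap
confidence intervals — i.e. everything needed for a per-species richness
summary table.

Estimator formulas and their variances follow the standard incidence-based
forms (Chao; Colwell & Coddington first-order jackknife) as implemented in
the ecological reference software:

* Chao2 (bias-corrected, small-sample factor A = (N-1)/N):
  ``S_obs + A*Q1^2/(2*Q2)`` when ``Q2 > 0``, else ``S_obs + A*Q1*(Q1-1)/2``.
* Jackknife1: ``S_obs + Q1*(N-1)/N``; its variance uses the per-sample counts
  of singleton ZOTUs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from .core import OccurrenceMatrix


@dataclass
class IncidenceFrequencies:
    """Incidence counts feeding the richness extrapolators.

    ``q1_per_sample`` (# of singleton ZOTUs whose one occurrence falls in each
    sample) is only needed for the jackknife SE; it is filled in when the
    frequencies are derived from a matrix.
    """

    s_obs: int
    q1: int
    q2: int
    n: int
    q1_per_sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.q1 + self.q2 > self.s_obs:
            raise ValueError("Q1 + Q2 cannot exceed S_obs")
        if self.n < 1:
            raise ValueError("need at least one sample")


def incidence_frequencies(matrix: OccurrenceMatrix, species: str) -> IncidenceFrequencies:
    """Incidence frequencies over one species' individuals.

    Restricted to ZOTUs with at least one presence in that species.
    """
    cols = matrix.species_columns(species)
    sub = matrix.presence[cols].to_numpy()
    inc = sub.sum(axis=1)
    present = inc > 0
    singleton_rows = inc == 1
    return IncidenceFrequencies(
        s_obs=int(present.sum()),
        q1=int(singleton_rows.sum()),
        q2=int((inc == 2).sum()),
        n=len(cols),
        q1_per_sample=sub[singleton_rows].sum(axis=0),
    )


def chao2(freq: IncidenceFrequencies, bias_corrected: bool = True):
    """Bias-corrected incidence-based Chao2 estimate and its SE.

    With ``bias_corrected=False`` the small-sample factor (N-1)/N is dropped
    (the classic form).
    """
    if freq.n < 2:
        raise ValueError("Chao2 requires at least 2 samples")
    s, q1, q2, n = freq.s_obs, freq.q1, freq.q2, freq.n
    a = (n - 1) / n if bias_corrected else 1.0
    if q2 > 0:
        est = s + a * q1 * q1 / (2 * q2)
        g = q1 / q2
        var = q1 * a * (0.5 + a * (1 + g / 4) * g) * g
    else:
        est = s + a * q1 * (q1 - 1) / 2
        if q1 > 0:
            var = a * (a * (q1 * (2 * q1 - 1) ** 2 / 4 - q1 ** 4 / est / 4)
                       + q1 * (q1 - 1) / 2)
        else:
            var = 0.0
    return float(est), float(math.sqrt(max(var, 0.0)))


def jackknife1(freq: IncidenceFrequencies):
    """First-order jackknife estimate and SE.

    The variance needs the per-sample singleton counts; when those are not
    available (hand-built frequencies) the SE is reported as NaN.
    """
    if freq.n < 2:
        raise ValueError("jackknife1 requires at least 2 samples")
    s, q1, n = freq.s_obs, freq.q1, freq.n
    est = s + q1 * (n - 1) / n
    if q1 == 0:
        return float(est), 0.0
    if freq.q1_per_sample is None:
        return float(est), float("nan")
    sj = np.asarray(freq.q1_per_sample, dtype=float)
    var = (np.sum(sj ** 2) - q1 / n) * (n - 1) / n
    return float(est), float(math.sqrt(max(var, 0.0)))


@dataclass
class AccumulationCurve:
    """Cumulative richness over randomized sample orderings."""

    curves: np.ndarray  # (n_rand, n_individuals)
    species: str

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)


def accumulation(matrix: OccurrenceMatrix, species: str, n_rand: int = 200,
                 seed=None) -> AccumulationCurve:
    """Sample-based accumulation: richness after 1..N individuals, averaged
    over ``n_rand`` random orderings of that species' individuals."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    cols = matrix.species_columns(species)
    sub = matrix.presence[cols].to_numpy().astype(bool)
    sub = sub[sub.any(axis=1)]
    n = len(cols)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_rand, n), dtype=np.int64)
    for b in range(n_rand):
        perm = rng.permutation(n)
        arr = sub[:, perm]
        first = arr.argmax(axis=1)  # index of first detection per ZOTU
        curves[b] = np.bincount(first, minlength=n).cumsum()
    return AccumulationCurve(curves=curves, species=species)


def species_span(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Per-ZOTU: set of host species occupied, its size, and uniqueness."""
    inc = matrix.species_incidence()
    present = inc > 0
    spans = present.apply(lambda row: tuple(s for s in inc.columns if row[s]), axis=1)
    return pd.DataFrame({
        "span": spans,
        "n_species": present.sum(axis=1),
        "unique": present.sum(axis=1) == 1,
    })


def unique_shared(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Per-species tallies of unique vs shared observed ZOTUs."""
    if len(matrix.species) < 2:
        raise ValueError("unique/shared partition needs at least 2 species")
    span = species_span(matrix)
    inc = matrix.species_incidence()
    rows = {}
    for sp in matrix.species:
        observed = inc[sp] > 0
        s_obs = int(observed.sum())
        uniq = int((observed & span["unique"]).sum())
        rows[sp] = {
            "s_obs": s_obs,
            "unique": uniq,
            "shared": s_obs - uniq,
            "prop_unique": uniq / s_obs if s_obs else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# BCa bootstrap


def bca_mean_interval(values, B: int = 10000, alpha: float = 0.05, seed=None,
                      return_diagnostics: bool = False):
    """BCa bootstrap confidence interval for the mean.

    The bias correction ``z0`` comes from the proportion of bootstrap means
    below the point estimate, counting ties as half; the acceleration ``a``
    from the jackknife skewness. When all values are equal the interval
    degenerates to the point.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("BCa interval needs at least 2 values")
    theta = float(x.mean())
    if np.ptp(x) == 0:
        if return_diagnostics:
            return theta, theta, theta, {"z0": 0.0, "a": 0.0, "boot": np.full(B, theta)}
        return theta, theta, theta
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot = x[idx].mean(axis=1)
    less = np.count_nonzero(boot < theta)
    equal = np.count_nonzero(boot == theta)
    p0 = (less + 0.5 * equal) / B
    p0 = min(max(p0, 0.5 / B), 1 - 0.5 / B)  # keep z0 finite
    z0 = float(ndtri(p0))
    # jackknife acceleration for the mean
    jk = (x.sum() - x) / (n - 1)
    d = jk.mean() - jk
    denom = np.sum(d ** 2) ** 1.5
    a = float(np.sum(d ** 3) / (6 * denom)) if denom > 0 else 0.0
    z_lo, z_hi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    alpha1 = float(norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo))))
    alpha2 = float(norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi))))
    lo, hi = np.quantile(boot, [alpha1, alpha2])
    if return_diagnostics:
        return theta, float(lo), float(hi), {"z0": z0, "a": a, "boot": boot}
    return theta, float(lo), float(hi)


def mean_incidence(matrix: OccurrenceMatrix, species: str, which: str,
                   B: int = 10000, seed=None):
    """Mean number of a species' individuals occupied by its unique (or
    shared) ZOTUs, with a BCa 95% CI bootstrapping over ZOTUs."""
    if which not in ("unique", "shared"):
        raise ValueError("which must be 'unique' or 'shared'")
    cols = matrix.species_columns(species)
    inc = matrix.presence[cols].sum(axis=1)
    span = species_span(matrix)
    observed = inc > 0
    mask = observed & (span["unique"] if which == "unique" else ~span["unique"])
    values = inc[mask].to_numpy()
    if values.size < 2:
        raise ValueError(
            f"fewer than 2 {which} ZOTUs observed for species {species!r}"
        )
    return bca_mean_interval(values, B=B, seed=seed)


def richness_summary(matrix: OccurrenceMatrix, B: int = 10000, seed=None) -> pd.DataFrame:
    """Per-species summary table: n, S_obs, unique partition, extrapolated
    richness (Chao2 and jackknife1 with SEs), and mean incidences of unique
    and shared ZOTUs with BCa 95% CIs."""
    us = unique_shared(matrix)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(matrix.species))
    rows = {}
    for i, sp in enumerate(matrix.species):
        freq = incidence_frequencies(matrix, sp)
        chao_est, chao_se = chao2(freq)
        jack_est, jack_se = jackknife1(freq)
        row = {
            "n": freq.n,
            "s_obs": freq.s_obs,
            "unique": int(us.loc[sp, "unique"]),
            "prop_unique": float(us.loc[sp, "prop_unique"]),
            "chao2": chao_est, "chao2_se": chao_se,
            "jack1": jack_est, "jack1_se": jack_se,
        }
        for j, which in enumerate(("unique", "shared")):
            try:
                m, lo, hi = mean_incidence(matrix, sp, which, B=B,
                                           seed=children[2 * i + j])
                row[f"mean_inc_{which}"] = m
                row[f"mean_inc_{which}_lo"] = lo
                row[f"mean_inc_{which}_hi"] = hi
            except ValueError:
                row[f"mean_inc_{which}"] = float("nan")
                row[f"mean_inc_{which}_lo"] = float("nan")
                row[f"mean_inc_{which}_hi"] = float("nan")
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index")
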