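"""Sloan neutral community model: fitting, prediction bands, partitioning.

The model predicts an OTU's occurrence frequency across hosts from its
mean relative abundance in the source pool.  Under neutral drift with
migration probability ``m`` into local communities of ``N`` individuals
(reads, post-rarefaction), the local relative abundance of an OTU with
pool abundance ``p`` follows Beta(N*m*p, N*m*(1-p)); the predicted
frequency of detection at limit ``d`` (one read, d = 1/N, by default) is

    f_hat(p) = 1 - BetaCDF(d; N*m*p, N*m*(1-p)).

``m`` is fit by least squares of the predicted against the observed
frequencies; ``Nm = N*m`` summarizes migration (higher = less dispersal
limitation).  By default the fit uses the *discrete* detection probability
under the same Beta latent distribution,

    f_det(p) = 1 - E[(1 - pi)^N],  pi ~ Beta(N*m*p, N*m*(1-p)),

i.e. the probability that at least one of N reads hits the OTU.  The
continuous threshold form above is its large-N approximation and is
available via ``model="beta-cdf"``; the discrete form removes the
approximation's systematic upward bias in fitted Nm.  OTUs are classed
above/within/below a Wilson 95% band around the prediction, and the fit
is compared by AIC to a binomial occurrence null ``f_bin = 1 - (1-p)^N``
with no free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln as betaln_
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .io import OtuTable


def occurrence_stats(table: OtuTable) -> pd.DataFrame:
    """Per-OTU mean relative abundance ``p`` and occurrence frequency ``f``.

    Requires a rarefied table (equal row sums).  OTUs never observed are
    dropped.
    """
    sums = table.sample_sums()
    if len(sums) == 0:
        raise ValueError("empty table")
    if np.unique(sums).size != 1:
        raise ValueError("unequal sample depths: rarefy the table first")
    n = int(sums[0])
    rel = table.counts / n
    p = rel.mean(axis=0)
    f = (table.counts >= 1).mean(axis=0)
    df = pd.DataFrame({"p": p, "f": f}, index=table.otu_ids)
    return df[df["f"] > 0].copy()


def predict_frequency(p, N: int, m: float, d: float | None = None) -> np.ndarray:
    """Neutral prediction of occurrence frequency at detection limit ``d``."""
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly in (0, 1)")
    if d is None:
        d = 1.0 / N
    nm = N * m
    return 1.0 - beta_dist.cdf(d, nm * p, nm * (1.0 - p))


def detect_probability(p, N: int, m: float) -> np.ndarray:
    """Exact probability of >= 1 read in N under the Beta latent model.

    1 - B(a, b+N)/B(a, b) with a = N*m*p, b = N*m*(1-p) — the
    beta-binomial zero-class complement.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly in (0, 1)")
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - np.exp(betaln_(a, b + N) - betaln_(a, b))


def binomial_frequency(p, N: int) -> np.ndarray:
    """Occurrence frequency if reads were binomial draws from the pool."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    return 1.0 - np.exp(N * np.log1p(-p))


@dataclass
class NeutralFit:
    m: float
    N: int
    Nm: float
    r_squared: float
    aic_neutral: float
    aic_binomial: float
    otus: pd.DataFrame  # p, f, predicted, ci_lower, ci_upper, class
    fraction_within: float
    fraction_above: float
    fraction_below: float


def fit_sloan(
    stats: pd.DataFrame,
    N: int,
    d: float | None = None,
    ci_level: float = 0.95,
    n_samples: int | None = None,
    model: str = "betabinom",
) -> NeutralFit:
    """Fit migration ``m`` and classify OTUs against the neutral band.

    ``stats`` is the output of :func:`occurrence_stats`.  ``model``
    chooses the prediction curve: ``"betabinom"`` (default) is the exact
    one-read detection probability; ``"beta-cdf"`` the continuous
    threshold approximation at limit ``d``.  The band is the Wilson score
    interval around the predicted frequency at the realized number of
    samples.  AIC uses the Gaussian least-squares form ``n*ln(SSE/n) + 2k``
    with k=1 for the neutral fit, k=0 for the zero-parameter binomial null.
    """
    stats = stats[(stats["p"] > 0) & (stats["p"] < 1)]
    if len(stats) < 10:
        raise ValueError("need at least 10 OTUs to fit the neutral model")
    p = stats["p"].to_numpy()
    f = stats["f"].to_numpy()
    n = len(p)
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("degenerate occurrence frequencies (no variance)")

    if model == "betabinom":
        def curve(m: float) -> np.ndarray:
            return detect_probability(p, N, m)
    elif model == "beta-cdf":
        def curve(m: float) -> np.ndarray:
            return predict_frequency(p, N, m, d)
    else:
        raise ValueError(f"unknown model {model!r}")

    def sse(m: float) -> float:
        return float(((f - curve(m)) ** 2).sum())

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded", options={"xatol": 1e-8})
    m = float(res.x)
    predicted = curve(m)
    sse_n = float(res.fun)
    r2 = 1.0 - sse_n / sst
    eps = 1e-12  # floor so a perfect fit does not send AIC to -inf
    aic_neutral = n * np.log(max(sse_n, eps) / n) + 2 * 1
    sse_b = float(((f - binomial_frequency(p, N)) ** 2).sum())
    aic_binomial = n * np.log(max(sse_b, eps) / n) + 2 * 0

    # Wilson band around the prediction, at the number of host samples
    # (inferred from the granularity f = k / n_samples when not given)
    if n_samples is None:
        n_samples = _infer_sample_count(f)
    lower, upper = proportion_confint(
        np.round(predicted * n_samples), n_samples, alpha=1 - ci_level, method="wilson"
    )
    cls = np.where(f > upper, "above", np.where(f < lower, "below", "within"))
    otus = stats.copy()
    otus["predicted"] = predicted
    otus["ci_lower"] = lower
    otus["ci_upper"] = upper
    otus["class"] = cls
    frac = otus["class"].value_counts(normalize=True)
    return NeutralFit(
        m=m,
        N=N,
        Nm=N * m,
        r_squared=float(r2),
        aic_neutral=float(aic_neutral),
        aic_binomial=float(aic_binomial),
        otus=otus,
        fraction_within=float(frac.get("within", 0.0)),
        fraction_above=float(frac.get("above", 0.0)),
        fraction_below=float(frac.get("below", 0.0)),
    )


def _infer_sample_count(f: np.ndarray) -> int:
    """Recover the sample count from observed frequencies f = k/n."""
    for n in range(1, 100001):
        if np.allclose(f * n, np.round(f * n), atol=1e-9):
            return n
    raise ValueError("could not infer sample count from frequencies")


def fit_sloan_table(
    table: OtuTable, d: float | None = None, ci_level: float = 0.95
) -> NeutralFit:
    """Convenience: occurrence stats + fit, with N = the rarefaction depth."""
    stats = occurrence_stats(table)
    N = int(table.sample_sums()[0])
    return fit_sloan(stats, N, d=d, ci_level=ci_level, n_samples=table.n_samples)


def partition_communities(table: OtuTable, fit: NeutralFit) -> tuple[OtuTable, OtuTable]:
    """Split the table into above-prediction and below-prediction OTU sets."""
    missing = [o for o in fit.otus.index if o not in set(table.otu_ids)]
    if missing:
        raise ValueError("fit does not correspond to this table")
    above = [o for o in table.otu_ids if o in fit.otus.index and fit.otus.at[o, "class"] == "above"]
    below = [o for o in table.otu_ids if o in fit.otus.index and fit.otus.at[o, "class"] == "below"]
    for name, ids in (("above", above), ("below", below)):
        if not ids:
            warnings.warn(f"no OTUs in the {name!r} partition", stacklevel=2)
    return table.select_otus(above), table.select_otus(below)
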