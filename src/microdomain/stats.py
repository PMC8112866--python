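"""Count and size-distribution statistics for membrane-microdomain data.

The scientific content of this module:

* **Poisson modelling of clusters per liposome.** If clusters nucleate
  independently, the number of clusters per liposome is Poisson with rate
  λ (clusters/liposome). :class:`PoissonRateModel` fits λ by maximum
  likelihood (the sample mean), attaches an exact gamma-based 95% CI on the
  total count, and runs a χ² goodness-of-fit test with bins pooled to an
  expected count of at least 5.

* **Exact two-sample Poisson rate comparison.** Conditional on the total
  count K = k1 + k2, k1 is Binomial(K, n1/(n1+n2)) under equal rates; the
  *C-test* computes an exact two-sided p-value by the minimum-likelihood
  method (summing all outcomes no more probable than the observed one).
  The unconditional *E-test* standardizes the rate difference and sums the
  joint Poisson probability, under the pooled rate estimate, of all
  outcomes at least as extreme; it is typically less conservative. Both are
  exchangeable under swapping the two groups.

* **Lognormal cluster-size analysis.** Cluster molecule counts spanning
  tens to hundreds are well described by a lognormal law; the fit is MLE on
  log-transformed data with a Kolmogorov-Smirnov diagnostic against the
  fitted normal. The KS p-value is computed against the fitted parameters
  without a Lilliefors correction and is therefore anti-conservative; this
  caveat is carried in the result metadata rather than silently corrected.

* **Frequency histograms** with a fixed bin width (default 2 molecules) and
  half-open bins, and **delegated group comparisons** (Student's t,
  one-way ANOVA with Tukey or Dunnett post hoc) via scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import ParameterError

__all__ = [
    "PoissonFitResult",
    "PoissonRateModel",
    "RateComparisonResult",
    "LognormalFitResult",
    "LognormalSizeModel",
    "HistogramSpec",
    "GroupComparisonResult",
    "fit_poisson",
    "compare_poisson_rates",
    "fit_lognormal",
    "frequency_histogram",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# Poisson fit
# ---------------------------------------------------------------------------

@dataclass
class PoissonFitResult:
    """MLE fit of a Poisson rate to per-liposome cluster counts."""

    lambda_hat: float
    n: int
    ci95: tuple[float, float]
    gof_chi2: float
    gof_p: float
    gof_df: int

    def summary(self) -> str:
        lines = [
            "Poisson rate fit (clusters per liposome)",
            "----------------------------------------",
            f"n liposomes     : {self.n}",
            f"lambda_hat (MLE): {self.lambda_hat:.4f}",
            f"95% CI (exact)  : [{self.ci95[0]:.4f}, {self.ci95[1]:.4f}]",
            f"GOF chi2        : {self.gof_chi2:.3f} (df={self.gof_df}), p={self.gof_p:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, counts: Optional[Sequence[int]] = None, ax=None):
        """Bar plot of observed count frequencies against the fitted pmf."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        kmax = max(5, int(sps.poisson.isf(1e-3, self.lambda_hat)))
        ks = np.arange(kmax + 1)
        if counts is not None:
            obs = np.bincount(np.asarray(counts, dtype=int), minlength=kmax + 1)[: kmax + 1]
            ax.bar(ks, obs / obs.sum(), color="0.7", label="observed")
        ax.plot(ks, sps.poisson.pmf(ks, self.lambda_hat), "ko-",
                label=f"Poisson(λ={self.lambda_hat:.2f})")
        ax.set_xlabel("clusters per liposome")
        ax.set_ylabel("frequency")
        ax.legend()
        return ax


class PoissonRateModel:
    """Poisson model for a sample of non-negative integer counts.

    ``PoissonRateModel(counts).fit()`` returns :class:`PoissonFitResult`.
    The MLE of the rate is the sample mean; the 95% CI is the exact
    gamma (chi-square) interval on the total count divided by n.
    """

    def __init__(self, counts: Sequence[int]):
        arr = np.asarray(counts)
        if arr.size == 0:
            raise ParameterError("counts must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("counts must be finite")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ParameterError("counts must be non-negative integers")
        self.counts = arr.astype(int)

    def fit(self) -> PoissonFitResult:
        counts = self.counts
        n = counts.size
        total = int(counts.sum())
        lam = total / n
        lo = 0.0 if total == 0 else sps.chi2.ppf(0.025, 2 * total) / 2.0 / n
        hi = sps.chi2.ppf(0.975, 2 * total + 2) / 2.0 / n
        chi2, p, df = self._gof(counts, lam)
        return PoissonFitResult(
            lambda_hat=lam, n=n, ci95=(lo, hi), gof_chi2=chi2, gof_p=p, gof_df=df
        )

    @staticmethod
    def _gof(counts: np.ndarray, lam: float) -> tuple[float, float, int]:
        """χ² goodness of fit with right-tail pooling to expected >= 5.

        One degree of freedom is spent on the estimated rate. Returns
        ``(nan, nan, 0)`` when fewer than three pooled bins remain.
        """
        n = counts.size
        if lam == 0:
            return float("nan"), float("nan"), 0
        kmax = int(counts.max())
        obs = np.bincount(counts, minlength=kmax + 2).astype(float)
        exp = n * sps.poisson.pmf(np.arange(kmax + 2), lam)
        exp[-1] = n * sps.poisson.sf(kmax, lam)  # lump the upper tail
        # pool from the right until every bin expects at least 5
        o, e = list(obs), list(exp)
        i = len(e) - 1
        while i > 0:
            if e[i] < 5.0:
                e[i - 1] += e[i]
                o[i - 1] += o[i]
                del e[i], o[i]
            i -= 1
        if e and e[0] < 5.0 and len(e) > 1:
            e[1] += e[0]
            o[1] += o[0]
            del e[0], o[0]
        df = len(e) - 2
        if df < 1:
            return float("nan"), float("nan"), 0
        chi2 = float(np.sum((np.array(o) - np.array(e)) ** 2 / np.array(e)))
        return chi2, float(sps.chi2.sf(chi2, df)), df


def fit_poisson(counts: Sequence[int]) -> PoissonFitResult:
    """Fit a Poisson rate to counts (MLE = sample mean, exact 95% CI)."""
    return PoissonRateModel(counts).fit()


# ---------------------------------------------------------------------------
# two-sample Poisson rate comparison
# ---------------------------------------------------------------------------

@dataclass
class RateComparisonResult:
    """Outcome of a two-sample Poisson rate test.

    ``k1, k2`` are the observed counts, ``n1, n2`` the exposures (here:
    numbers of liposomes). ``statistic`` is the observed first-group count
    for the conditional C-test and the standardized rate difference for the
    E-test. ``degenerate`` marks the k1 + k2 = 0 case, where p = 1 by
    convention.
    """

    method: str
    statistic: float
    p_two_sided: float
    k1: int
    k2: int
    n1: float
    n2: float
    degenerate: bool = False

    @property
    def rate1(self) -> float:
        return self.k1 / self.n1

    @property
    def rate2(self) -> float:
        return self.k2 / self.n2

    def summary(self) -> str:
        lines = [
            f"Two-sample Poisson rate comparison ({self.method})",
            "-------------------------------------------------",
            f"group 1: k={self.k1}, exposure={self.n1:g}, rate={self.rate1:.4f}",
            f"group 2: k={self.k2}, exposure={self.n2:g}, rate={self.rate2:.4f}",
            f"statistic        : {self.statistic:.4f}",
            f"two-sided p      : {self.p_two_sided:.3e}",
        ]
        if self.degenerate:
            lines.append("note: no events in either group; p = 1 by convention")
        return "\n".join(lines)


def _ctest_p(k1: int, K: int, q: float) -> float:
    """Exact two-sided binomial p by the minimum-likelihood method."""
    pmf = sps.binom.pmf(np.arange(K + 1), K, q)
    p_obs = pmf[k1]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-12)].sum()))


def _etest_p(k1: int, n1: float, k2: int, n2: float) -> tuple[float, float]:
    """Unconditional E-test: standardized difference, lattice summation.

    The null rate is the pooled estimate; the joint Poisson probability of
    all outcome pairs whose |standardized difference| is at least the
    observed one is summed, truncating the lattice where the marginal mass
    is below 1e-13 per tail.
    """
    lam = (k1 + k2) / (n1 + n2)

    def t_stat(x1, x2):
        var = x1 / n1**2 + x2 / n2**2
        diff = x1 / n1 - x2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, diff / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        return t

    t_obs = float(t_stat(np.array(k1, dtype=float), np.array(k2, dtype=float)))
    m1, m2 = n1 * lam, n2 * lam
    a1 = int(sps.poisson.ppf(1e-13, m1)) if m1 > 0 else 0
    b1 = int(sps.poisson.isf(1e-13, m1)) + 1 if m1 > 0 else 0
    a2 = int(sps.poisson.ppf(1e-13, m2)) if m2 > 0 else 0
    b2 = int(sps.poisson.isf(1e-13, m2)) + 1 if m2 > 0 else 0
    x1 = np.arange(a1, b1 + 1)
    x2 = np.arange(a2, b2 + 1)
    pmf1 = sps.poisson.pmf(x1, m1)
    pmf2 = sps.poisson.pmf(x2, m2)
    tt = t_stat(x1[:, None].astype(float), x2[None, :].astype(float))
    mask = np.abs(tt) >= abs(t_obs) - 1e-10
    p = float(np.sum(pmf1[:, None] * pmf2[None, :] * mask))
    return t_obs, min(1.0, p)


def compare_poisson_rates(
    k1: int, n1: float, k2: int, n2: float, method: str = "ctest"
) -> RateComparisonResult:
    """Exact (C-test) or unconditional (E-test) two-sample Poisson rate test.

    Parameters
    ----------
    k1, k2 : int
        Event counts (e.g. total clusters) in each group.
    n1, n2 : float
        Exposures (e.g. numbers of liposomes). Must be positive.
    method : {"ctest", "etest"}
    """
    if method not in ("ctest", "etest"):
        raise ParameterError("method must be 'ctest' or 'etest'")
    if k1 < 0 or k2 < 0 or int(k1) != k1 or int(k2) != k2:
        raise ParameterError("counts must be non-negative integers")
    if not (n1 > 0 and n2 > 0):
        raise ParameterError("exposures must be positive")
    k1, k2 = int(k1), int(k2)
    if k1 + k2 == 0:
        warnings.warn("no events in either group; p = 1 by convention", stacklevel=2)
        return RateComparisonResult(
            method=method, statistic=0.0, p_two_sided=1.0,
            k1=k1, k2=k2, n1=n1, n2=n2, degenerate=True,
        )
    if method == "ctest":
        K = k1 + k2
        q = n1 / (n1 + n2)
        p = _ctest_p(k1, K, q)
        stat = float(k1)
    else:
        stat, p = _etest_p(k1, n1, k2, n2)
    return RateComparisonResult(
        method=method, statistic=stat, p_two_sided=p, k1=k1, k2=k2, n1=n1, n2=n2
    )


# ---------------------------------------------------------------------------
# lognormal size fit
# ---------------------------------------------------------------------------

@dataclass
class LognormalFitResult:
    """MLE lognormal fit with a KS diagnostic.

    ``mean_arith = exp(mu_log + sigma_log^2 / 2)`` and
    ``median_arith = exp(mu_log)``. The KS p-value uses the fitted
    parameters without a Lilliefors correction (anti-conservative; see
    ``ks_caveat``). ``degenerate`` marks samples with (near-)zero log
    spread, where sigma sits on the boundary and the KS test is undefined.
    """

    mu_log: float
    sigma_log: float
    n: int
    ks_stat: float
    ks_p: float
    degenerate: bool = False
    ks_caveat: str = (
        "KS computed against fitted parameters without Lilliefors correction; "
        "p-value is anti-conservative"
    )

    @property
    def mean_arith(self) -> float:
        return math.exp(self.mu_log + self.sigma_log**2 / 2.0)

    @property
    def median_arith(self) -> float:
        return math.exp(self.mu_log)

    def summary(self) -> str:
        lines = [
            "Lognormal size fit (MLE on log data)",
            "------------------------------------",
            f"n               : {self.n}",
            f"mu_log          : {self.mu_log:.4f}",
            f"sigma_log       : {self.sigma_log:.4f}",
            f"median (arith)  : {self.median_arith:.3f}",
            f"mean (arith)    : {self.mean_arith:.3f}",
            f"KS stat         : {self.ks_stat:.4f}, p={self.ks_p:.4f}",
            f"note            : {self.ks_caveat}",
        ]
        if self.degenerate:
            lines.append("note: zero log-spread; sigma at boundary, KS undefined")
        return "\n".join(lines)

    def plot(self, sizes: Optional[Sequence[float]] = None, bin_width: float = 2.0, ax=None):
        """Frequency histogram of sizes with the fitted lognormal density."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if sizes is not None:
            arr = np.asarray(sizes, dtype=float)
            edges = np.arange(
                math.floor(arr.min() / bin_width) * bin_width,
                arr.max() + 2 * bin_width,
                bin_width,
            )
            ax.hist(arr, bins=edges, density=True, color="0.8", label="data")
            xmax = arr.max() * 1.2
        else:
            xmax = self.mean_arith * 4
        x = np.linspace(1e-6, xmax, 400)
        pdf = sps.lognorm.pdf(x, s=self.sigma_log, scale=math.exp(self.mu_log))
        ax.plot(x, pdf, "k-", label="lognormal fit")
        ax.set_xlabel("cluster size (molecules)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class LognormalSizeModel:
    """Lognormal model for positive size data (cluster molecule counts).

    ``LognormalSizeModel(sizes).fit()`` returns :class:`LognormalFitResult`.
    """

    def __init__(self, sizes: Sequence[float]):
        arr = np.asarray(sizes, dtype=float)
        if arr.size < 3:
            raise ParameterError("need at least 3 sizes to fit a lognormal")
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ParameterError("all sizes must be finite and positive")
        self.sizes = arr

    def fit(self) -> LognormalFitResult:
        logx = np.log(self.sizes)
        mu = float(logx.mean())
        sigma = float(logx.std(ddof=0))  # MLE
        if sigma < 1e-12:
            return LognormalFitResult(
                mu_log=mu, sigma_log=0.0, n=logx.size,
                ks_stat=float("nan"), ks_p=float("nan"), degenerate=True,
            )
        ks = sps.kstest(logx, "norm", args=(mu, sigma))
        return LognormalFitResult(
            mu_log=mu, sigma_log=sigma, n=logx.size,
            ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        )


def fit_lognormal(sizes: Sequence[float]) -> LognormalFitResult:
    """MLE lognormal fit on log-transformed data with a KS diagnostic."""
    return LognormalSizeModel(sizes).fit()


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class HistogramSpec:
    """A fixed-width frequency histogram with half-open bins [edge, edge+w).

    When ``bin_edges`` is None, :func:`frequency_histogram` derives edges
    from the data, anchored at an integer multiple of ``bin_width``.
    """

    bin_width: float = 2.0
    bin_edges: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.bin_width > 0):
            raise ParameterError("bin_width must be positive")
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            if edges.ndim != 1 or edges.size < 2:
                raise ParameterError("bin_edges must be a 1-D array of >= 2 edges")
            spacing = np.diff(edges)
            if np.any(spacing <= 0):
                raise ParameterError("bin_edges must be strictly increasing")
            if not np.allclose(spacing, self.bin_width, rtol=1e-9, atol=1e-9):
                raise ParameterError("bin_edges must be spaced by bin_width")
            self.bin_edges = edges

    @property
    def n_bins(self) -> int:
        return 0 if self.bin_edges is None else self.bin_edges.size - 1


def frequency_histogram(sizes: Sequence[float], spec: HistogramSpec) -> HistogramSpec:
    """Fill a fixed-width frequency histogram; bins are half-open.

    Samples outside the edge range are dropped (the sum of counts equals
    the number of in-range samples).
    """
    arr = np.asarray(sizes, dtype=float)
    w = spec.bin_width
    if spec.bin_edges is None:
        if arr.size == 0:
            edges = np.array([0.0, w])
        else:
            e0 = math.floor(arr.min() / w) * w
            n_bins = int(math.floor((arr.max() - e0) / w)) + 1
            edges = e0 + w * np.arange(n_bins + 1)
    else:
        edges = spec.bin_edges
    n_bins = edges.size - 1
    counts = np.zeros(n_bins, dtype=int)
    if arr.size:
        idx = np.floor((arr - edges[0]) / w).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, idx[ok], 1)
    return HistogramSpec(bin_width=w, bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# delegated group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """Multiplicity-adjusted p-values from a standard group comparison."""

    test: str
    p_values: dict[str, float]
    estimates: dict[str, float]

    def summary(self) -> str:
        lines = [f"Group comparison: {self.test}", "-" * 30]
        for label, m in self.estimates.items():
            lines.append(f"mean[{label}] = {m:.4f}")
        for label, p in self.p_values.items():
            lines.append(f"p[{label}] = {p:.4g}")
        return "\n".join(lines)


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    test: str = "t_two_tailed",
    control_label: Optional[str] = None,
) -> GroupComparisonResult:
    """Student's t, or one-way ANOVA with Tukey / Dunnett post hoc (scipy).

    ``samples`` maps group labels to observations. Dunnett requires
    ``control_label``; its adjusted p-values cover every non-control group.
    """
    labels = list(samples.keys())
    arrays = [np.asarray(samples[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ParameterError("need at least two groups")
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise ParameterError(f"group {lab!r} has fewer than 2 observations")
    estimates = {lab: float(a.mean()) for lab, a in zip(labels, arrays)}

    if test == "t_two_tailed":
        if len(arrays) != 2:
            raise ParameterError("t-test requires exactly two groups")
        a, b = arrays
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        key = f"{labels[0]} vs {labels[1]}"
        return GroupComparisonResult(test=test, p_values={key: p}, estimates=estimates)

    if test == "anova_tukey":
        res = sps.tukey_hsd(*arrays)
        p_values = {}
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                p_values[f"{labels[i]} vs {labels[j]}"] = float(res.pvalue[i, j])
        return GroupComparisonResult(test=test, p_values=p_values, estimates=estimates)

    if test == "anova_dunnett":
        if control_label is None or control_label not in samples:
            raise ParameterError("anova_dunnett requires a valid control_label")
        others = [lab for lab in labels if lab != control_label]
        res = sps.dunnett(
            *[np.asarray(samples[lab], dtype=float) for lab in others],
            control=np.asarray(samples[control_label], dtype=float),
        )
        p_values = {
            f"{lab} vs {control_label}": float(p) for lab, p in zip(others, res.pvalue)
        }
        return GroupComparisonResult(test=test, p_values=p_values, estimates=estimates)

    raise ParameterError("test must be 't_two_tailed', 'anova_tukey' or 'anova_dunnett'")
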