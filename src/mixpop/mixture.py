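"""Binned Gaussian-mixture deconvolution of log2 expression distributions.

The model is a sum of up to three Gaussian curves fitted directly to the
binned frequency distribution by unweighted nonlinear least squares:

    y(x) = sum_i A_i * exp(-0.5 * ((x - m_i) / s_i)^2)

where y is the observed count in the bin centred at x, A_i the component
amplitude (counts at the peak), m_i its mean and s_i its standard
deviation, all in log2 expression units. The area under component i,
AUC_i = A_i * s_i * sqrt(2*pi), is proportional to the number of patients
in that sub-population, so normalized AUCs give sub-population weights.

Fitting is multi-start (quantile-seeded means with seeded jitter); a fit
counts as converged when at least two starts agree to a relative parameter
tolerance and no component has collapsed. Model selection over 1..3
components uses small-sample AIC on the Gaussian residual likelihood.
Normality diagnostics (Probit coordinates and a Lilliefors-type
Kolmogorov-Smirnov test) justify the mixture over a single normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

_SQRT2PI = math.sqrt(2.0 * math.pi)


class FitError(RuntimeError):
    """Mixture fitting could not produce a usable result."""


@dataclass
class BinnedFrequency:
    """Histogram of log2 values: constant-width, half-open bins.

    Counts are integers for real histograms but may be fractional when a
    frequency curve is evaluated directly (noiseless model input).
    """

    bin_width: float
    left_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.left_edges = np.asarray(self.left_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if len(self.left_edges) != len(self.counts):
            raise ValueError("edges and counts lengths differ")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if len(self.left_edges) > 1:
            gaps = np.diff(self.left_edges)
            if not np.allclose(gaps, self.bin_width, rtol=0, atol=1e-9):
                raise ValueError("bin edges must ascend with constant spacing")

    @property
    def centers(self) -> np.ndarray:
        return self.left_edges + self.bin_width / 2.0

    @property
    def n_total(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian curve: peak amplitude (counts), mean and SD (log2 units)."""

    amplitude: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sd <= 0:
            raise ValueError("amplitude and SD must be positive")


@dataclass
class MixtureFit:
    """Result of fitting a sum of Gaussians to binned frequencies."""

    components: list[GaussianComponent]
    predicted_counts: np.ndarray
    ss_residual: float
    syx: float
    pearson_r_obs_pred: float
    aucs: np.ndarray
    weights: np.ndarray
    converged: bool
    n_starts_used: int
    seed: int
    candidates: dict = field(default_factory=dict, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])


def bin_values(values, bin_width: float = 0.2, anchor: float = 0.0) -> BinnedFrequency:
    """Histogram ``values`` into half-open bins [k*w, (k+1)*w) anchored at 0.

    Empty interior bins are retained so the regression sees the full
    support; counts always sum to the number of input values.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least two values to bin")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    # small forward nudge keeps values sitting exactly on an edge in the
    # right-hand bin despite floating-point division error
    idx = np.floor((arr - anchor) / bin_width + 1e-9).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    left_edges = anchor + np.arange(lo, hi + 1) * bin_width
    return BinnedFrequency(bin_width=bin_width, left_edges=left_edges, counts=counts)


def gaussian_sum(x, components) -> np.ndarray | float:
    """Model prediction y(x) = sum_i A_i exp(-0.5 ((x-m_i)/s_i)^2)."""
    xv = np.asarray(x, dtype=float)
    total = np.zeros_like(xv, dtype=float)
    for c in components:
        total = total + c.amplitude * np.exp(-0.5 * ((xv - c.mean) / c.sd) ** 2)
    return total if total.ndim else float(total)


def component_auc(component: GaussianComponent) -> float:
    """Area under one Gaussian curve, A * SD * sqrt(2*pi), in patients."""
    return component.amplitude * component.sd * _SQRT2PI


def _components_from_params(params: np.ndarray) -> list[GaussianComponent]:
    comps = [
        GaussianComponent(amplitude=params[3 * i], mean=params[3 * i + 1], sd=params[3 * i + 2])
        for i in range(len(params) // 3)
    ]
    return sorted(comps, key=lambda c: c.mean)


def _sorted_params(params: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [[c.amplitude, c.mean, c.sd] for c in _components_from_params(params)]
    )


def fit_mixture(
    freq: BinnedFrequency, n_components: int, n_starts: int = 3, seed: int = 0
) -> MixtureFit:
    """Fit a sum of ``n_components`` Gaussians to binned counts.

    Least-squares minimisation of the raw count residuals over bin centres,
    with positivity bounds on amplitudes and SDs. Component means are
    seeded at interior quantiles of the (histogram-reconstructed) value
    distribution, with seeded uniform jitter for the additional starts.
    The fit is flagged converged when at least two starts reach parameter
    vectors agreeing within a relative tolerance of 1e-3 and every
    component keeps at least 1% of the total area; the reported solution
    is the lowest-SSE start satisfying those conditions.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    if freq.n_bins <= 3 * n_components:
        raise FitError(
            f"{freq.n_bins} bins cannot identify {n_components} components "
            f"(need more than {3 * n_components})"
        )
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")

    x = freq.centers
    y = freq.counts.astype(float)
    n = freq.n_total
    rng = np.random.default_rng(seed)

    # approximate raw values from the histogram for quantile seeding
    pseudo = np.repeat(x, np.round(freq.counts).astype(int))
    if pseudo.size == 0:
        raise FitError("empty histogram")
    qs = (2 * np.arange(1, n_components + 1) - 1) / (2 * n_components)
    mean_seeds = np.quantile(pseudo, qs)
    sd_seed = max(np.std(pseudo), freq.bin_width)
    sd0 = max(sd_seed / n_components, freq.bin_width / 2)
    amp0 = max(y.max(), 1.0) / n_components

    lo_edge, hi_edge = freq.left_edges[0], freq.left_edges[-1] + freq.bin_width
    lower = np.tile([1e-8, lo_edge - 2.0, 1e-4], n_components)
    upper = np.tile([10.0 * max(y.max(), 1.0), hi_edge + 2.0, hi_edge - lo_edge + 1.0],
                    n_components)

    def residuals(p: np.ndarray) -> np.ndarray:
        return gaussian_sum(x, _components_from_params_unchecked(p)) - y

    def _components_from_params_unchecked(p):
        return [_Raw(p[3 * i], p[3 * i + 1], p[3 * i + 2]) for i in range(n_components)]

    solutions = []  # (sse, sorted params, valid_weights)
    for s in range(n_starts):
        jitter = np.zeros(n_components) if s == 0 else rng.uniform(
            -2 * freq.bin_width, 2 * freq.bin_width, n_components
        )
        x0 = np.empty(3 * n_components)
        x0[0::3] = amp0
        x0[1::3] = np.clip(mean_seeds + jitter, lower[1], upper[1])
        x0[2::3] = sd0
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lower, upper), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        if not res.success:
            continue
        p = _sorted_params(res.x)
        aucs = p[0::3] * p[2::3] * _SQRT2PI
        valid = bool(np.all(aucs / aucs.sum() >= 0.01))
        solutions.append((float(np.sum(res.fun**2)), p, valid))

    if not solutions:
        raise FitError("no optimization start succeeded")

    def _agree(a: np.ndarray, b: np.ndarray) -> bool:
        return bool(np.all(np.abs(a - b) / np.maximum(np.abs(b), 1e-8) < 1e-3))

    converged_set = []
    for i, (sse_i, p_i, valid_i) in enumerate(solutions):
        if not valid_i:
            continue
        for j, (_, p_j, valid_j) in enumerate(solutions):
            if i != j and valid_j and _agree(p_i, p_j):
                converged_set.append((sse_i, p_i))
                break

    if converged_set:
        sse, params = min(converged_set, key=lambda t: t[0])
        converged = True
    else:
        sse, params, _ = min(solutions, key=lambda t: t[0])
        converged = False

    components = _components_from_params(params)
    predicted = gaussian_sum(x, components)
    dof = freq.n_bins - 3 * n_components
    syx = math.sqrt(sse / dof) if dof > 0 else math.nan
    if np.std(predicted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, predicted)[0, 1])
    else:
        r = math.nan
    aucs = np.array([component_auc(c) for c in components])
    return MixtureFit(
        components=components,
        predicted_counts=np.asarray(predicted),
        ss_residual=float(sse),
        syx=syx,
        pearson_r_obs_pred=r,
        aucs=aucs,
        weights=aucs / aucs.sum(),
        converged=converged,
        n_starts_used=len(solutions),
        seed=seed,
    )


class _Raw:
    """Unvalidated component used inside the optimizer loop."""

    __slots__ = ("amplitude", "mean", "sd")

    def __init__(self, amplitude, mean, sd):
        self.amplitude = amplitude
        self.mean = mean
        self.sd = sd


def select_model(
    freq: BinnedFrequency, max_components: int = 3, n_starts: int = 3, seed: int = 0
) -> MixtureFit:
    """Fit 1..max_components Gaussians and pick the best converged model.

    A candidate is valid when it converged, no component holds less than
    1% of the area, and no SD has collapsed below half a bin width. Among
    valid candidates the small-sample corrected AIC decides, computed
    from the Poisson likelihood of the observed bin counts under the
    fitted curve: bin counts are Poisson-distributed, so high-count bins
    carry far more noise than tail bins, and a Gaussian-residual
    criterion would reward extra components for absorbing that noise.
    All candidates are kept on the returned fit for inspection.
    """
    candidates: dict[int, MixtureFit] = {}
    best: tuple[float, MixtureFit] | None = None
    for m in range(1, max_components + 1):
        if freq.n_bins <= 3 * m:
            break
        try:
            fit = fit_mixture(freq, m, n_starts=n_starts, seed=seed)
        except FitError:
            continue
        candidates[m] = fit
        if not fit.converged:
            continue
        if np.any(fit.weights < 0.01):
            continue
        if any(c.sd < freq.bin_width / 2 for c in fit.components):
            continue
        n = freq.n_bins
        k = 3 * m
        mu = np.clip(fit.predicted_counts, 1e-9, None)
        y = freq.counts
        loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
        aic = -2.0 * loglik + 2 * k
        aicc = aic + (2 * k * (k + 1) / (n - k - 1)) if n - k - 1 > 0 else math.inf
        if best is None or aicc < best[0]:
            best = (aicc, fit)
    if best is None:
        raise FitError("no converged mixture candidate for 1..%d components" % max_components)
    fit = best[1]
    fit.candidates = candidates
    return fit


@dataclass
class NormalityResult:
    """Kolmogorov-Smirnov distance and p-value of a normality test."""

    ks_distance: float
    p_value: float


def ks_normality(values, seed: int = 0, n_boot: int = 10000) -> NormalityResult:
    """Lilliefors-type K-S test of composite normality.

    D is the supremum distance between the empirical CDF and a normal CDF
    with mean and SD estimated from the sample. Because the parameters are
    estimated, the plain Kolmogorov distribution is invalid; the p-value
    uses the Dallal-Wilkinson approximation (with the large-n rescaling
    above n = 100), falling back to a parametric bootstrap for n < 30.
    """
    arr = np.sort(np.asarray(values, dtype=float).ravel())
    n = arr.size
    if n < 5:
        raise ValueError("need at least 5 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    d = _lilliefors_d(arr, n)
    if n < 30:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_boot):
            sim = np.sort(rng.normal(size=n))
            if _lilliefors_d(sim, n) >= d:
                exceed += 1
        p = (exceed + 1) / (n_boot + 1)
    else:
        p = _dallal_wilkinson(d, n)
    return NormalityResult(ks_distance=float(d), p_value=float(min(max(p, 0.0), 1.0)))


def _lilliefors_d(sorted_values: np.ndarray, n: int) -> float:
    m = sorted_values.mean()
    s = sorted_values.std(ddof=1)
    z = stats.norm.cdf((sorted_values - m) / s)
    i = np.arange(1, n + 1)
    return float(max((i / n - z).max(), (z - (i - 1) / n).max()))


def _dallal_wilkinson(d: float, n: int) -> float:
    if n > 100:
        d = d * (n / 100.0) ** 0.49
        n = 100
    return math.exp(
        -7.01256 * d * d * (n + 2.78019)
        + 2.99587 * d * math.sqrt(n + 2.78019)
        - 0.122119
        + 0.974598 / math.sqrt(n)
        + 1.67997 / n
    )


def probit_coordinates(values) -> tuple[np.ndarray, np.ndarray]:
    """Ordered sample values paired with standard-normal quantiles.

    Uses the (i - 0.5)/n plotting position; the pairs fall on a straight
    line exactly when the sample comes from a single normal distribution.
    """
    arr = np.sort(np.asarray(values, dtype=float).ravel())
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values")
    quantiles = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return arr, quantiles
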