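"""Hard-window assignment of patients to expression sub-populations.

Patients are labelled low / intermediate / high when their index-gene
log2 value falls inside one of three disjoint cut-off windows; values in
the gaps stay unassigned. Because the fitted Gaussian components overlap,
a window intended for one component also captures tails of the others;
the expected misassignment percentage per window follows in closed form
from the normal CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .mixture import MixtureFit

LABELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class Window:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lo) & (v <= self.hi)  # closed interval


@dataclass(frozen=True)
class SubpopulationScheme:
    """Three disjoint, ascending cut-off windows in log2 units."""

    low: Window
    intermediate: Window
    high: Window

    def __post_init__(self) -> None:
        if not (self.low.hi < self.intermediate.lo and self.intermediate.hi < self.high.lo):
            raise ValueError("windows must be pairwise disjoint and ascending")

    @property
    def windows(self) -> tuple[Window, Window, Window]:
        return (self.low, self.intermediate, self.high)


@dataclass
class AssignmentResult:
    labels: np.ndarray
    misassignment_pct: dict


def default_scheme() -> SubpopulationScheme:
    """The published cut-off windows: 5-6.5, 7.25-8.5 and 10-13 log2 units."""
    return SubpopulationScheme(
        low=Window(5.0, 6.5),
        intermediate=Window(7.25, 8.5),
        high=Window(10.0, 13.0),
    )


def assign(values, scheme: SubpopulationScheme | None = None) -> np.ndarray:
    """Label each value by the window containing it, else ``unassigned``."""
    scheme = scheme or default_scheme()
    v = np.asarray(values, dtype=float)
    labels = np.full(v.shape, "unassigned", dtype=object)
    for name, window in zip(LABELS, scheme.windows):
        labels[window.contains(v)] = name
    return labels


def misassignment(
    fit: MixtureFit,
    scheme: SubpopulationScheme | None = None,
    population_sizes=None,
    n_total: int | None = None,
) -> dict:
    """Expected percent of each window's occupants from the wrong component.

    For window W targeted at component k, the expected occupants from
    component j are N_j * [Phi((hi - m_j)/s_j) - Phi((lo - m_j)/s_j)];
    the misassignment percentage is the share of occupants with j != k.
    ``population_sizes`` defaults to the AUC-derived weights scaled to
    ``n_total`` (or to the total fitted area).
    """
    scheme = scheme or default_scheme()
    if fit.n_components != 3:
        raise ValueError("misassignment requires a 3-component fit")
    if not fit.converged:
        raise ValueError("misassignment requires a converged fit")
    if population_sizes is None:
        total = float(n_total) if n_total is not None else float(fit.aucs.sum())
        population_sizes = fit.weights * total
    sizes = np.asarray(population_sizes, dtype=float)
    if sizes.shape != (3,):
        raise ValueError("population_sizes must have one entry per component")

    out: dict[str, float] = {}
    for k, (name, window) in enumerate(zip(LABELS, scheme.windows)):
        occupants = np.array(
            [
                sizes[j]
                * (
                    norm.cdf((window.hi - c.mean) / c.sd)
                    - norm.cdf((window.lo - c.mean) / c.sd)
                )
                for j, c in enumerate(fit.components)
            ]
        )
        total = occupants.sum()
        if total <= 0:
            raise ValueError(f"window {name} has zero expected occupancy")
        out[name] = 100.0 * (total - occupants[k]) / total
    return out


def assignment_result(
    values,
    fit: MixtureFit | None = None,
    scheme: SubpopulationScheme | None = None,
    n_total: int | None = None,
) -> AssignmentResult:
    """Labels plus (when a converged 3-component fit is given) misassignment."""
    scheme = scheme or default_scheme()
    labels = assign(values, scheme)
    mis: dict = {}
    if fit is not None and fit.n_components == 3 and fit.converged:
        mis = misassignment(fit, scheme, n_total=n_total or len(np.asarray(values).ravel()))
    return AssignmentResult(labels=labels, misassignment_pct=mis)
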