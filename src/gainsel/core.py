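"""Domain types and validation for index-selection pipelines.

The package works on a fixed, ordered trait panel. All vectors and matrices
are expressed in panel order; readers align labelled inputs to this order
before anything numerical happens. Units are carried as strings and never
converted — desired gains, responses and economic values are always in the
trait's native unit (days, grams per plant, percentage points, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

log = logging.getLogger("gainsel")

#: relative tolerance for symmetry / PSD checks on covariance matrices
SYM_RTOL = 1e-8

GainMode = Literal["absolute", "percent"]


class ValidationError(ValueError):
    """Raised when a panel, matrix or scenario violates its invariants."""


@dataclass(frozen=True)
class TraitPanel:
    """An ordered panel of traits with units and current population means.

    Parameters
    ----------
    names
        Unique trait identifiers; their order is canonical for every vector
        and matrix in the pipeline.
    units
        Per-trait unit strings (``d``, ``g``, ``cm``, ``%``, scores, ...).
    means
        Current population mean per trait, in trait units. Percent-of-mean
        desired gains and the relative-change columns of reports are taken
        against these values.
    reference
        The trait whose economic value is fixed at 1 when normalising
        implied economic values (dry biomass per plant by default). Resolved
        by exact name or, failing that, by unique prefix, so ``DryMatter``
        finds ``DryMatter.9``.
    """

    names: tuple[str, ...]
    units: tuple[str, ...]
    means: np.ndarray
    reference: str = "DryMatter"

    def __init__(
        self,
        names: Sequence[str],
        units: Sequence[str],
        means: Sequence[float],
        reference: str = "DryMatter",
    ) -> None:
        names = tuple(str(n) for n in names)
        units = tuple(str(u) for u in units)
        means_arr = np.asarray(means, dtype=float)
        if len(names) == 0:
            raise ValidationError("trait panel is empty")
        if any(not n for n in names):
            raise ValidationError("trait names must be non-empty")
        if len(set(names)) != len(names):
            raise ValidationError("trait names must be unique")
        if not (len(names) == len(units) == means_arr.shape[0]):
            raise ValidationError(
                f"panel fields disagree in length: {len(names)} names, "
                f"{len(units)} units, {means_arr.shape[0]} means"
            )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "means", means_arr)
        object.__setattr__(self, "reference", reference)
        self.resolve(reference)  # reference trait must exist

    @property
    def n(self) -> int:
        return len(self.names)

    def resolve(self, trait: str) -> str:
        """Return the canonical panel name for ``trait``.

        Exact matches win; otherwise a unique prefix match is accepted.
        """
        if trait in self.names:
            return trait
        hits = [n for n in self.names if n.startswith(trait)]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise ValidationError(f"trait {trait!r} not in panel")
        raise ValidationError(f"trait {trait!r} is ambiguous: matches {hits}")

    def index_of(self, trait: str) -> int:
        return self.names.index(self.resolve(trait))

    @property
    def reference_index(self) -> int:
        return self.index_of(self.reference)


@dataclass(frozen=True)
class GeneticParameters:
    """Additive genetic (G) and phenotypic (P) covariance matrices.

    Both are n x n in panel order, in squared trait units. The residual
    covariance is E = P - G; validity requires G and E positive
    semi-definite and per-trait heritability G_jj / P_jj in (0, 1].
    """

    G: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        P = np.atleast_2d(np.asarray(self.P, dtype=float))
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "P", P)
        if G.shape != P.shape or G.shape[0] != G.shape[1]:
            raise ValidationError(
                f"G and P must be square and equal-shaped, got {G.shape} and {P.shape}"
            )

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def E(self) -> np.ndarray:
        """Residual (environmental) covariance, P - G."""
        return self.P - self.G

    @property
    def heritabilities(self) -> np.ndarray:
        """Per-trait h^2 = G_jj / P_jj."""
        return np.diag(self.G) / np.diag(self.P)


@dataclass(frozen=True)
class Gain:
    """A single desired-gain entry: trait, value and how to read the value.

    ``percent`` values are percentages of the current population mean and
    are converted to absolute trait units before solving; ``absolute``
    values are already in trait units. Zero is legal in either mode and
    means "hold this trait unchanged".
    """

    trait: str
    value: float
    mode: GainMode = "absolute"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "percent"):
            raise ValidationError(f"unknown gain mode {self.mode!r}")


@dataclass(frozen=True)
class Scenario:
    """A named set of desired genetic gains on a subset of panel traits."""

    name: str
    gains: tuple[Gain, ...]

    def __init__(self, name: str, gains: Sequence[Gain]) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "gains", tuple(gains))
        if not self.gains:
            raise ValidationError(f"scenario {name!r} has no desired gains")

    def validate(self, panel: TraitPanel) -> "Scenario":
        """Resolve trait names against ``panel`` and check uniqueness."""
        resolved = [replace(g, trait=panel.resolve(g.trait)) for g in self.gains]
        seen: set[str] = set()
        for g in resolved:
            if g.trait in seen:
                raise ValidationError(
                    f"scenario {self.name!r}: duplicate gain for trait {g.trait!r}"
                )
            seen.add(g.trait)
        return Scenario(self.name, resolved)


@dataclass(frozen=True)
class IndexSolution:
    """Everything the index machinery produces for one scenario.

    Attributes
    ----------
    b : index weights, one per panel trait (index units per trait unit).
    a : implied economic values (reference-trait units per unit change).
    Q_star : expected single-generation responses, all traits, trait units.
    sigma_I : standard deviation of the index, sqrt(b' P b).
    i : required selection intensity (= sigma_I under the single-generation
        assumption).
    p : selected upper-tail fraction implied by i under normal truncation
        selection.
    """

    b: np.ndarray
    a: np.ndarray
    Q_star: np.ndarray
    sigma_I: float
    i: float
    p: float


@dataclass(frozen=True)
class EconomicAssumptions:
    """Stand density and biomass price used to monetise trait changes."""

    density: float = 4444.0  # plants per hectare (1.5 x 1.5 m grid)
    price: float = 70.0  # currency per tonne dry biomass
    grams_per_tonne: float = 1e6
    currency: str = "€"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValidationError("plant density must be positive")
        if self.price < 0:
            raise ValidationError("price must be non-negative")


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > SYM_RTOL * scale:
        raise ValidationError(f"{name} is not symmetric (relative tolerance {SYM_RTOL})")
    return 0.5 * (M + M.T)


def _psd_floor(M: np.ndarray, name: str, repair: bool) -> np.ndarray:
    """Check PSD-ness; with ``repair`` clip negative eigenvalues instead."""
    w, V = np.linalg.eigh(M)
    wmax = max(w.max(), 0.0)
    tol = SYM_RTOL * max(wmax, 1.0)
    if w.min() >= 0.0:
        return M
    if w.min() < -tol and not repair:
        raise ValidationError(
            f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g}); "
            "pass psd_repair=True to clip"
        )
    if not repair:  # negative but within tolerance: leave untouched
        return M
    eps = SYM_RTOL * wmax
    w_clipped = np.clip(w, eps, None)
    log.warning(
        "PSD repair on %s: clipped %d eigenvalue(s), most negative %.3g",
        name, int((w < eps).sum()), w.min(),
    )
    repaired = V @ np.diag(w_clipped) @ V.T
    return 0.5 * (repaired + repaired.T)


def validate_parameters(
    panel: TraitPanel,
    params: GeneticParameters,
    psd_repair: bool = False,
) -> GeneticParameters:
    """Validate (and optionally repair) G and P against the panel.

    Symmetry is enforced by averaging each matrix with its transpose. With
    ``psd_repair`` negative eigenvalues of G and of E = P - G are clipped to
    a small positive floor (1e-8 of the largest eigenvalue) with a logged
    warning — marker-estimated covariance matrices are often slightly
    indefinite; by default the check is strict so data errors are not
    silently masked. Heritabilities outside (0, 1] are always rejected.

    The operation is idempotent: validated parameters pass unchanged.
    """
    if params.n != panel.n:
        raise ValidationError(
            f"parameter matrices are {params.n}x{params.n} but panel has {panel.n} traits"
        )
    G = _check_symmetric(params.G, "G")
    P = _check_symmetric(params.P, "P")

    Pd = np.diag(P)
    if np.any(Pd <= 0):
        bad = [panel.names[j] for j in np.flatnonzero(Pd <= 0)]
        raise ValidationError(f"non-positive phenotypic variance for {bad}")
    h2 = np.diag(G) / Pd
    if np.any(h2 <= 0) or np.any(h2 > 1 + SYM_RTOL):
        bad = [
            f"{panel.names[j]} (h2={h2[j]:.4f})"
            for j in np.flatnonzero((h2 <= 0) | (h2 > 1 + SYM_RTOL))
        ]
        raise ValidationError(f"heritability > 1 or <= 0 for {bad}")

    G = _psd_floor(G, "G", psd_repair)
    E = _psd_floor(P - G, "E = P - G", psd_repair)
    return GeneticParameters(G=G, P=G + E)


def absolute_gains(
    scenario: Scenario, panel: TraitPanel
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a scenario's desired gains to absolute trait units.

    Returns ``(Q, mask)`` where ``mask`` holds the panel indices of the
    constrained traits in panel order and ``Q`` the corresponding desired
    gains in trait units: percent entries become pct/100 * mean, absolute
    entries pass through.
    """
    scenario = scenario.validate(panel)
    by_trait = {g.trait: g for g in scenario.gains}
    idx = sorted(panel.index_of(t) for t in by_trait)
    q = np.empty(len(idx))
    for k, j in enumerate(idx):
        g = by_trait[panel.names[j]]
        if g.mode == "percent":
            mu = panel.means[j]
            if mu == 0:
                raise ValidationError(
                    f"percent gain on trait {g.trait!r} with zero mean"
                )
            q[k] = g.value / 100.0 * mu
        else:
            q[k] = g.value
    return q, np.asarray(idx, dtype=int)
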