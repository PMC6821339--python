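"""Synthetic breeding populations with realistic covariance structure.

Real marker-estimated G and P matrices live in supplementary spreadsheets
and are population-specific; this module builds valid stand-ins with the
statistical structure the index machinery assumes, so every pipeline stage
is testable end to end, and simulates clonally replicated populations for
Monte-Carlo validation of predicted responses.

The default panel emulates a 16-trait *Miscanthus sinensis* evaluation:
two phenology traits, eleven morphology/biomass traits and three cell-wall
composition traits, with published broad-sense heritabilities (0.48-0.89),
a weak flowering-yield genetic correlation (0.19) and strong flowering-
senescence / flowering-moisture genetic correlations (|r| = 0.85). It is an
emulation of that structure, not a reproduction of any estimated matrix:
correlations the literature does not state are small defaults, and the
phenotypic SDs are set to a uniform 20 % coefficient of variation.

Covariances are assembled from heritabilities, phenotypic SDs and separate
genetic/environmental correlation matrices:

    G = D_g r_g D_g,  D_g = diag(sd_p * sqrt(h2))
    E = D_e r_e D_e,  D_e = diag(sd_p * sqrt(1 - h2))
    P = G + E

which recovers h2 = G_jj / P_jj exactly by construction.

Note on heritability semantics: the published H^2 values are broad-sense,
while the index equations treat G as additive; the simulator follows the
source analysis in treating the generated G as additive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GeneticParameters, TraitPanel, ValidationError, validate_parameters

log = logging.getLogger("gainsel")

# trait, unit, current mean, broad-sense H2, group
_DEFAULT_TRAITS = [
    ("DOYFS1.9", "d", 221.21, 0.89, "phenology"),
    ("AvgeSen.9", "score 0-10", 7.34, 0.83, "phenology"),
    ("BaseDiameter.9", "mm", 398.72, 0.52, "morphology"),
    ("DryMatter.9", "g", 1065.47, 0.54, "morphology"),
    ("LeafLength.7", "cm", 52.43, 0.65, "morphology"),
    ("LeafWidth.7", "cm", 1.42, 0.64, "morphology"),
    ("MaxCanopyHeight.9", "cm", 144.67, 0.77, "morphology"),
    ("Moisture.9", "%", 30.65, 0.59, "morphology"),
    ("StatureLeafAngle.7", "score 0-1", 0.66, 0.50, "morphology"),
    ("StatureStemAngle.7", "score 1-4", 1.97, 0.48, "morphology"),
    ("StemDiameter.9", "mm", 5.37, 0.60, "morphology"),
    ("TallestStem.9", "cm", 176.82, 0.88, "morphology"),
    ("TransectCount.9", "count", 27.63, 0.51, "morphology"),
    ("Cellulose.8", "%", 42.14, 0.79, "cellwall"),
    ("Hemicellulose.8", "%", 32.81, 0.60, "cellwall"),
    ("Lignin.8", "%", 8.95, 0.66, "cellwall"),
]

# stated pairwise genetic correlations; delayed flowering goes with higher
# moisture and lower senescence score, hence the signs
_STATED_RG = {
    ("DOYFS1.9", "DryMatter.9"): 0.19,
    ("DOYFS1.9", "AvgeSen.9"): -0.85,
    ("DOYFS1.9", "Moisture.9"): 0.85,
    ("AvgeSen.9", "Moisture.9"): -0.70,  # implied by the two strong links above
    ("MaxCanopyHeight.9", "DryMatter.9"): 0.30,
    ("TallestStem.9", "DryMatter.9"): 0.30,
}

#: small default correlations for pairs the literature does not state
_RG_WITHIN_GROUP = 0.20
_RG_BETWEEN_GROUP = 0.05
_RE_WITHIN_GROUP = 0.10
#: default phenotypic coefficient of variation (sd_p = 0.2 * mean)
_DEFAULT_CV = 0.20


@dataclass(frozen=True)
class CovarianceSpec:
    """Heritabilities, phenotypic SDs and correlation structure for a panel."""

    h2: np.ndarray  # per-trait heritability in (0, 1]
    sd_p: np.ndarray  # per-trait phenotypic SD, trait units
    r_g: np.ndarray  # n x n genetic correlation matrix
    r_e: np.ndarray  # n x n environmental correlation matrix

    def __post_init__(self) -> None:
        h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        sd_p = np.atleast_1d(np.asarray(self.sd_p, dtype=float))
        r_g = np.atleast_2d(np.asarray(self.r_g, dtype=float))
        r_e = np.atleast_2d(np.asarray(self.r_e, dtype=float))
        for name, arr in (("h2", h2), ("sd_p", sd_p)):
            if arr.ndim != 1 or arr.shape[0] != h2.shape[0]:
                raise ValidationError(f"{name} must be a vector matching the panel")
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise ValidationError("heritabilities must be in (0, 1]")
        if np.any(sd_p <= 0):
            raise ValidationError("phenotypic SDs must be positive")
        for name, R in (("r_g", r_g), ("r_e", r_e)):
            if R.shape != (h2.shape[0], h2.shape[0]):
                raise ValidationError(f"{name} must be n x n")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValidationError(f"{name} must have unit diagonal")
            if np.abs(R - R.T).max() > 1e-10 or np.abs(R).max() > 1 + 1e-10:
                raise ValidationError(f"{name} must be symmetric with entries in [-1, 1]")
        object.__setattr__(self, "h2", h2)
        object.__setattr__(self, "sd_p", sd_p)
        object.__setattr__(self, "r_g", r_g)
        object.__setattr__(self, "r_e", r_e)

    @property
    def n(self) -> int:
        return self.h2.shape[0]


@dataclass(frozen=True)
class SyntheticPopulation:
    """True breeding values and replicated phenotypes for N genotypes.

    ``tbv`` is N x n (zero-mean multivariate normal with covariance G);
    ``phenotypes`` is N x n x reps with phenotype = mean + tbv + residual,
    residuals drawn per replicate with covariance E = P - G (a balanced
    clonal-replicate design).
    """

    ids: tuple[str, ...]
    means: np.ndarray  # panel means mu, length n
    tbv: np.ndarray  # N x n
    phenotypes: np.ndarray  # N x n x reps
    seed: int

    @property
    def n_genotypes(self) -> int:
        return self.tbv.shape[0]

    @property
    def reps(self) -> int:
        return self.phenotypes.shape[2]

    @property
    def genotype_means(self) -> np.ndarray:
        """Phenotypes averaged over replicates, N x n."""
        return self.phenotypes.mean(axis=2)


def build_covariances(spec: CovarianceSpec, psd_repair: bool = False) -> GeneticParameters:
    """Assemble G and P from a covariance spec.

    G = D_g r_g D_g and E = D_e r_e D_e with D_g = diag(sd_p sqrt(h2)),
    D_e = diag(sd_p sqrt(1 - h2)); P = G + E, so the per-trait heritability
    of the result equals ``spec.h2`` exactly (up to traits with h2 = 1,
    whose residual variance is zero).
    """
    d_g = spec.sd_p * np.sqrt(spec.h2)
    d_e = spec.sd_p * np.sqrt(1.0 - spec.h2)
    G = spec.r_g * np.outer(d_g, d_g)
    E = spec.r_e * np.outer(d_e, d_e)
    params = GeneticParameters(G=G, P=G + E)
    panel = TraitPanel(
        names=[f"t{j}" for j in range(spec.n)],
        units=["?"] * spec.n,
        means=np.ones(spec.n),
        reference="t0",
    )
    return validate_parameters(panel, params, psd_repair=psd_repair)


def _nearest_correlation(R: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a PSD correlation matrix.

    Eigenvalue clipping followed by diagonal renormalisation; adequate for
    the mildly indefinite matrices pairwise defaults can produce.
    """
    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-10:
        return R
    w = np.clip(w, 1e-8 * w.max(), None)
    M = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return 0.5 * (M + M.T)


def default_panel() -> tuple[TraitPanel, CovarianceSpec]:
    """The 16-trait emulation panel and its covariance spec.

    Means and broad-sense heritabilities follow the published evaluation
    of 138 *M. sinensis* genotypes; stated genetic correlations are set
    explicitly and all unstated ones default to 0.2 within a trait group
    (phenology / morphology / cell wall) and 0.05 between groups — small
    rather than zero so the genetic covariance is full-rank. Environmental
    correlations default to 0.1 within groups, 0 between. The assembled
    genetic correlation matrix is projected to the nearest PSD correlation
    matrix if the pairwise defaults leave it slightly indefinite.
    """
    names = [t[0] for t in _DEFAULT_TRAITS]
    units = [t[1] for t in _DEFAULT_TRAITS]
    means = np.array([t[2] for t in _DEFAULT_TRAITS])
    h2 = np.array([t[3] for t in _DEFAULT_TRAITS])
    groups = [t[4] for t in _DEFAULT_TRAITS]
    n = len(names)

    r_g = np.full((n, n), _RG_BETWEEN_GROUP)
    r_e = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if groups[j] == groups[k]:
                r_g[j, k] = _RG_WITHIN_GROUP
                r_e[j, k] = _RE_WITHIN_GROUP
    idx = {name: j for j, name in enumerate(names)}
    for (t1, t2), r in _STATED_RG.items():
        r_g[idx[t1], idx[t2]] = r_g[idx[t2], idx[t1]] = r
    np.fill_diagonal(r_g, 1.0)
    np.fill_diagonal(r_e, 1.0)
    r_g = _nearest_correlation(r_g)
    r_e = _nearest_correlation(r_e)

    panel = TraitPanel(names=names, units=units, means=means, reference="DryMatter")
    spec = CovarianceSpec(h2=h2, sd_p=_DEFAULT_CV * means, r_g=r_g, r_e=r_e)
    return panel, spec


def simulate_population(
    params: GeneticParameters,
    means: np.ndarray,
    n_genotypes: int,
    reps: int = 1,
    seed: int = 20_180_338,
) -> SyntheticPopulation:
    """Draw a clonally replicated population from (G, E = P - G).

    Breeding values are N(0, G); each of ``reps`` replicate phenotypes adds
    an independent N(0, E) residual to mean + breeding value. Reproducible
    for a fixed seed (one generator drives the whole population).
    """
    means = np.asarray(means, dtype=float)
    if n_genotypes < 2 or reps < 1:
        raise ValidationError("need n_genotypes >= 2 and reps >= 1")
    if means.shape[0] != params.n:
        raise ValidationError("means length does not match parameter dimension")
    rng = np.random.default_rng(seed)
    n = params.n
    tbv = rng.multivariate_normal(np.zeros(n), params.G, size=n_genotypes,
                                  method="eigh")
    E = params.E
    if np.abs(E).max() == 0.0:
        resid = np.zeros((n_genotypes, n, reps))
    else:
        resid = rng.multivariate_normal(
            np.zeros(n), E, size=(n_genotypes, reps), method="eigh"
        ).transpose(0, 2, 1)
    phenotypes = means[None, :, None] + tbv[:, :, None] + resid
    ids = tuple(f"g{j:05d}" for j in range(n_genotypes))
    return SyntheticPopulation(ids=ids, means=means, tbv=tbv,
                               phenotypes=phenotypes, seed=seed)


def estimate_covariances(pop: SyntheticPopulation) -> tuple[np.ndarray, np.ndarray]:
    """Moment estimators (G_hat, P_hat) from a replicated population.

    Classical balanced one-way decomposition: the pooled within-genotype
    covariance estimates E; the among-genotype covariance of clone means
    estimates G + E/reps, so G_hat = Cov(means) - E_hat/reps and
    P_hat = G_hat + E_hat. Both are unbiased; used for parameter-recovery
    testing, not inside the analytical pipeline.
    """
    if pop.reps < 2:
        raise ValidationError("covariance estimation needs reps >= 2")
    N, n, r = pop.phenotypes.shape
    geno_means = pop.genotype_means  # N x n
    dev = pop.phenotypes - geno_means[:, :, None]  # within-genotype deviations
    flat = dev.transpose(0, 2, 1).reshape(N * r, n)
    E_hat = flat.T @ flat / (N * (r - 1))
    G_hat = np.cov(geno_means, rowvar=False, ddof=1) - E_hat / r
    return G_hat, G_hat + E_hat


def realized_response(
    pop: SyntheticPopulation, b: np.ndarray, p: float
) -> np.ndarray:
    """Realised genetic gains from truncation selection on the index.

    Scores genotype-mean phenotypes with I = b'X, keeps the top
    ceil(p * N) (ties broken by stable genotype order), and returns the
    selected group's mean true breeding value minus the population mean
    breeding value — the Monte-Carlo counterpart of the predicted response
    G b.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"selected fraction must be in (0, 1), got {p}")
    b = np.asarray(b, dtype=float)
    scores = pop.genotype_means @ b
    if np.ptp(scores) == 0.0:
        log.warning("degenerate selection: all index scores equal")
    n_sel = int(np.ceil(p * pop.n_genotypes))
    # stable sort on negated scores keeps genotype order within ties
    order = np.argsort(-scores, kind="stable")
    selected = order[:n_sel]
    return pop.tbv[selected].mean(axis=0) - pop.tbv.mean(axis=0)
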