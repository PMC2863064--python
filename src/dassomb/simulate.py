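"""Two-locus epistatic disease models and case-control data simulation.

Three standard two-locus models are supported, each defined by a 3×3
table of disease odds over the genotype combinations at two loci A and
B, parameterised by a baseline effect ``alpha0`` and a genotypic effect
``theta`` (with multiplier ``1 + theta``):

* model 1 — multiplicative: odds = alpha0 * (1+theta)^(g_A + g_B);
  the loci contribute independently (additive on the log-odds scale).
* model 2 — epistatic: odds = alpha0 unless both loci carry at least
  one disease allele, in which case odds = alpha0 * (1+theta)^(g_A*g_B).
* model 3 — threshold: odds = alpha0 * (1+theta) whenever both loci
  carry at least one disease allele, alpha0 otherwise; extra disease
  alleles do not further increase the risk.

Penetrance is odds/(1+odds). Given a target marginal effect ``lambda_``
(the multiplicative increase of the marginal disease odds per first
disease allele at a locus), a minor allele frequency and a population
prevalence, ``calibrate`` numerically solves for (alpha0, theta).

Simulated datasets mirror a typical power study: the two disease loci
are latent; each is observed through a genotyped marker in linkage
disequilibrium with it (squared correlation ``ld_r2``, coupling phase,
marker MAF equal to the disease MAF, so r² = 1 means the marker is an
exact copy); the remaining markers are independent noise SNPs in HWE
with MAFs drawn uniformly from (0, 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import CaseControlDataset

MODEL_IDS = (1, 2, 3)


class CalibrationError(RuntimeError):
    """No (alpha0, theta) solves the prevalence/marginal-effect system."""


@dataclass
class DiseaseModelSpec:
    """A calibrated two-locus disease model."""

    model_id: int
    baseline_effect: float  # alpha0 > 0
    genotypic_effect: float  # theta > -1
    odds: np.ndarray  # 3x3, indexed (g_A, g_B)
    penetrance: np.ndarray  # odds / (1 + odds)


@dataclass
class SimConfig:
    """Parameters of one simulated case-control study."""

    model_id: int
    marginal_effect: float  # lambda
    maf_disease: float
    ld_r2: float = 1.0
    prevalence: float = 0.1
    n_cases: int = 1000
    n_controls: int = 1000
    n_markers: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if not 0.0 < self.maf_disease <= 0.5:
            raise ValueError("maf_disease must be in (0, 0.5]")
        if not 0.0 < self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in (0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers (the two disease markers)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """HWE genotype probabilities ((1-q)^2, 2q(1-q), q^2) for q = maf."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def odds_table(model_id: int, alpha0: float, theta: float) -> np.ndarray:
    """3×3 disease-odds table for the given model, indexed (g_A, g_B)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"model_id must be one of {MODEL_IDS}")
    if alpha0 <= 0:
        raise ValueError("baseline effect must be positive")
    if theta <= -1:
        raise ValueError("genotypic effect must exceed -1")
    m = 1.0 + theta
    ga, gb = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if model_id == 1:
        exponent = ga + gb
    elif model_id == 2:
        exponent = ga * gb
    else:  # model 3: plateau once both loci carry a disease allele
        exponent = ((ga >= 1) & (gb >= 1)).astype(int)
    return alpha0 * m**exponent


def _penetrance(odds: np.ndarray) -> np.ndarray:
    return odds / (1.0 + odds)


def _population_quantities(
    model_id: int, alpha0: float, theta: float, maf: float
) -> tuple[np.ndarray, float, float]:
    """Penetrance table, population prevalence, and marginal odds ratio.

    The marginal odds ratio is odds_marg(Aa)/odds_marg(AA) where
    odds_marg(g) = p_g/(1-p_g) and p_g = Σ_gB pen(g, gB) P(gB); the two
    loci are unlinked and in HWE in the population.
    """
    probs = hwe_genotype_probs(maf)
    pen = _penetrance(odds_table(model_id, alpha0, theta))
    prevalence = float(probs @ pen @ probs)
    p_marg = pen @ probs  # P(disease | g_A), length 3
    # During root bracketing the penetrance can saturate at 1; the
    # resulting inf/nan ratio only steers the bracket, never a solution.
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_marg = p_marg / (1.0 - p_marg)
        ratio = float(odds_marg[1] / odds_marg[0])
    return pen, prevalence, ratio


def _solve_alpha0(model_id: int, theta: float, maf: float, prevalence: float) -> float:
    """alpha0 achieving the target prevalence at fixed theta (monotone)."""

    def residual(log_a: float) -> float:
        return (
            _population_quantities(model_id, math.exp(log_a), theta, maf)[1]
            - prevalence
        )

    lo, hi = -40.0, 40.0
    if residual(lo) > 0 or residual(hi) < 0:
        raise CalibrationError(
            f"no baseline effect reaches prevalence {prevalence} "
            f"(model {model_id}, theta={theta}, maf={maf})"
        )
    log_a = optimize.brentq(residual, lo, hi, xtol=1e-15, rtol=1e-15)
    return math.exp(log_a)


def calibrate(
    model_id: int,
    lambda_: float,
    maf: float,
    prevalence: float = 0.1,
    tol: float = 1e-10,
) -> DiseaseModelSpec:
    """Solve for (alpha0, theta) matching prevalence and marginal effect.

    The two conditions are (i) the population prevalence implied by the
    penetrance table under HWE equals ``prevalence``, and (ii) the
    marginal disease odds satisfy odds_marg(Aa) = (1 + lambda_) *
    odds_marg(AA) at each locus. Solved by nested Brent root-finding
    (alpha0 inner, theta outer); residuals are verified to ``tol``.
    """
    if lambda_ < 0:
        raise ValueError("marginal effect lambda must be nonnegative")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")

    def ratio_residual(theta: float) -> float:
        alpha0 = _solve_alpha0(model_id, theta, maf, prevalence)
        return _population_quantities(model_id, alpha0, theta, maf)[2] - (1.0 + lambda_)

    if abs(ratio_residual(0.0)) < tol:  # lambda == 0: exact closed form
        theta = 0.0
    else:
        hi = 1.0
        while ratio_residual(hi) < 0:
            hi *= 2.0
            if hi > 1e8:
                raise CalibrationError(
                    f"marginal effect {lambda_} unreachable "
                    f"(model {model_id}, maf={maf}, prevalence={prevalence})"
                )
        theta = optimize.brentq(ratio_residual, 0.0, hi, xtol=1e-14, rtol=1e-15)
    alpha0 = _solve_alpha0(model_id, theta, maf, prevalence)

    pen, prev, ratio = _population_quantities(model_id, alpha0, theta, maf)
    if abs(prev - prevalence) > tol or abs(ratio - (1.0 + lambda_)) > tol:
        raise CalibrationError(
            f"calibration residuals too large: prevalence {prev}, ratio {ratio}"
        )
    return DiseaseModelSpec(
        model_id=model_id,
        baseline_effect=alpha0,
        genotypic_effect=theta,
        odds=odds_table(model_id, alpha0, theta),
        penetrance=pen,
    )


def genotype_probs_given_status(
    spec: DiseaseModelSpec, maf: float
) -> tuple[np.ndarray, np.ndarray]:
    """P(g_A, g_B | case) and P(g_A, g_B | control), each a 3×3 table.

    Bayes inversion of the penetrance model against the HWE population
    distribution of the two (unlinked) disease loci.
    """
    probs = hwe_genotype_probs(maf)
    joint = np.outer(probs, probs)
    case = spec.penetrance * joint
    control = (1.0 - spec.penetrance) * joint
    return case / case.sum(), control / control.sum()


def ld_haplotype_freqs(p_d: float, p_m: float, r2: float) -> np.ndarray:
    """Haplotype frequencies (dm, dM, Dm, DM) at the target r².

    Lowercase = minor alleles at the disease locus (d) and marker (m).
    The coupling phase is used: D = +sqrt(r² p_d(1-p_d) p_m(1-p_m)).
    Raises if any implied haplotype frequency leaves [0, 1].
    """
    if not (0.0 < p_d < 1.0 and 0.0 < p_m < 1.0):
        raise ValueError("allele frequencies must be in (0, 1)")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must be in [0, 1]")
    d = math.sqrt(r2 * p_d * (1 - p_d) * p_m * (1 - p_m))
    freqs = np.array(
        [
            p_d * p_m + d,
            p_d * (1 - p_m) - d,
            (1 - p_d) * p_m - d,
            (1 - p_d) * (1 - p_m) + d,
        ]
    )
    if (freqs < -1e-12).any() or (freqs > 1 + 1e-12).any():
        raise ValueError(
            f"r2={r2} with p_d={p_d}, p_m={p_m} implies haplotype "
            "frequencies outside [0, 1]"
        )
    return np.clip(freqs, 0.0, 1.0)


def _marker_emission_probs(p_d: float, r2: float) -> tuple[float, float]:
    """P(marker minor allele | disease allele) for minor (d) and major (D).

    The marker MAF equals the disease MAF, so at r² = 1 the marker is an
    exact copy of the disease locus.
    """
    f_dm, f_dM, f_Dm, f_DM = ld_haplotype_freqs(p_d, p_d, r2)
    # Clip rounding spill (e.g. 1 + 2e-16 at r^2 = 1) back into [0, 1].
    return (
        float(np.clip(f_dm / p_d, 0.0, 1.0)),
        float(np.clip(f_Dm / (1.0 - p_d), 0.0, 1.0)),
    )


@dataclass
class SimulatedStudy:
    """A simulated dataset plus its ground truth."""

    dataset: CaseControlDataset
    truth: tuple[str, str]  # ids of the two disease-associated markers
    spec: DiseaseModelSpec
    disease_genotypes: np.ndarray = field(repr=False)  # latent, (n, 2)


def simulate_dataset(
    cfg: SimConfig, spec: DiseaseModelSpec | None = None
) -> SimulatedStudy:
    """Simulate one case-control study under ``cfg``.

    A calibrated ``spec`` may be passed to skip recalibration when many
    datasets share the same model parameters. Samples are ordered cases
    first. All randomness derives from ``cfg.seed``; there are no
    missing genotypes.
    """
    if spec is None:
        spec = calibrate(
            cfg.model_id, cfg.marginal_effect, cfg.maf_disease, cfg.prevalence
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls

    # Latent disease-locus genotype pairs, sampled per disease status.
    p_case, p_control = genotype_probs_given_status(spec, cfg.maf_disease)
    cells_case = rng.choice(9, size=cfg.n_cases, p=p_case.ravel())
    cells_ctrl = rng.choice(9, size=cfg.n_controls, p=p_control.ravel())
    cells = np.concatenate([cells_case, cells_ctrl])
    disease_g = np.column_stack([cells // 3, cells % 3]).astype(np.int8)

    # Observed markers: each of a locus' two alleles emits a marker
    # allele through the haplotype model.
    p_m_given_d, p_m_given_D = _marker_emission_probs(cfg.maf_disease, cfg.ld_r2)
    markers = np.empty((n, 2), dtype=np.int8)
    for locus in range(2):
        g = disease_g[:, locus].astype(np.int64)
        markers[:, locus] = rng.binomial(g, p_m_given_d) + rng.binomial(
            2 - g, p_m_given_D
        )

    # Noise SNPs: HWE, MAF ~ Uniform(0, 0.5), independent of status.
    n_noise = cfg.n_markers - 2
    noise_mafs = rng.uniform(0.0, 0.5, size=n_noise)
    noise = rng.binomial(2, np.broadcast_to(noise_mafs, (n, n_noise))).astype(np.int8)

    # Place the disease markers at random column positions.
    positions = rng.choice(cfg.n_markers, size=2, replace=False)
    genotypes = np.empty((n, cfg.n_markers), dtype=np.int8)
    noise_cols = [j for j in range(cfg.n_markers) if j not in set(positions)]
    genotypes[:, noise_cols] = noise
    genotypes[:, positions[0]] = markers[:, 0]
    genotypes[:, positions[1]] = markers[:, 1]

    snp_ids = [f"SNP{j + 1}" for j in range(cfg.n_markers)]
    dataset = CaseControlDataset(
        genotypes=genotypes,
        phenotype=np.concatenate(
            [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
        ),
        snp_ids=snp_ids,
        sample_ids=[f"S{i + 1}" for i in range(n)],
    )
    truth = (snp_ids[positions[0]], snp_ids[positions[1]])
    return SimulatedStudy(
        dataset=dataset, truth=truth, spec=spec, disease_genotypes=disease_g
    )
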