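"""Power for a single-SNP additive association test on a quantitative trait.

For an additive linear model on a trait where one SNP explains a fraction
``r2`` of the variance, the two-sided Wald/score test statistic is
asymptotically noncentral chi-square with 1 degree of freedom and
noncentrality ``ncp = n * r2 / (1 - r2)``.  Power at significance level
``alpha`` is the upper tail of that distribution beyond the central
chi-square critical value.  A simulation route (Hardy-Weinberg genotypes,
ordinary least squares per replicate) serves as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from windupkit.errors import ParameterError

__all__ = ["PowerSpec", "analytic_power", "simulated_power", "SimulatedPower"]

#: Genome-wide significance level used in the association analyses.
GENOME_WIDE_ALPHA = 5.3e-8


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a power calculation.

    ``r2`` is the proportion of trait variance explained by the SNP;
    ``alpha`` the two-sided significance level.
    """

    n: int
    r2: float
    alpha: float = GENOME_WIDE_ALPHA

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError("n must be at least 3")
        if not 0.0 <= self.r2 < 1.0:
            raise ParameterError("r2 must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SimulatedPower:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    se: float
    reps: int
    redraws: int  # monomorphic genotype draws that were replaced


def analytic_power(spec: PowerSpec) -> float:
    """Noncentral chi-square power of the 1-df association test."""
    ncp = spec.n * spec.r2 / (1.0 - spec.r2)
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(spec.alpha)


def simulated_power(
    spec: PowerSpec,
    maf: float = 0.3,
    reps: int = 5000,
    seed: int | None = None,
) -> SimulatedPower:
    """Estimate power by simulating genotype-trait replicates.

    Per replicate, genotypes 0/1/2 are drawn under Hardy-Weinberg at minor
    allele frequency ``maf``, the SNP effect is scaled so it explains
    ``r2`` of the trait variance against unit-variance normal residuals,
    and a two-sided t-test of the OLS slope is run at ``alpha``.
    Monomorphic draws are redrawn (counted in ``redraws``).
    """
    if not 0.0 < maf < 0.5:
        raise ParameterError("maf must lie in (0, 0.5)")
    if reps < 100:
        raise ParameterError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    n = spec.n
    var_g = 2.0 * maf * (1.0 - maf)
    # residual variance 1 => beta chosen so beta^2 var_g / (beta^2 var_g + 1) = r2
    beta = np.sqrt(spec.r2 / (1.0 - spec.r2) / var_g) if spec.r2 > 0 else 0.0
    p_geno = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df=n - 2)

    hits = 0
    redraws = 0
    for _ in range(reps):
        while True:
            g = rng.choice(3, size=n, p=p_geno).astype(float)
            if g.std() > 0:
                break
            redraws += 1
        y = beta * g + rng.standard_normal(n)
        gc = g - g.mean()
        yc = y - y.mean()
        sxx = float(gc @ gc)
        b = float(gc @ yc) / sxx
        resid = yc - b * gc
        s2 = float(resid @ resid) / (n - 2)
        tstat = b / np.sqrt(s2 / sxx)
        if abs(tstat) > t_crit:
            hits += 1
    p_hat = hits / reps
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / reps))
    return SimulatedPower(power=p_hat, se=se, reps=reps, redraws=redraws)
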