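"""Statistical recipes for the auction analyses.

Pearson correlations, the low/high start-price bin comparison with a
pooled-variance t test, paired condition comparisons with a normality
pre-check, empirical CDFs, and default Jeffreys–Zellner–Siow (JZS) Bayes
factors computed by direct numerical integration (Cauchy prior with scale
sqrt(2)/2 on the standardised effect).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "StatResult",
    "correlate",
    "split_by_start_price",
    "two_sample_t",
    "jzs_bf_ttest",
    "compare_paired_conditions",
    "Ecdf",
    "ecdf",
    "repeated_measures_anova",
]

JZS_DEFAULT_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: estimate, test statistic, df, p and Bayes factor."""

    estimate: float
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    bf10: float | None = None
    log_bf10: float | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bf10 is not None and self.bf10 <= 0:
            raise ValueError("bf10 must be positive")
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "bf10": self.bf10,
            "log_bf10": self.log_bf10,
            "method": self.method,
        }
        d.update(self.extra)
        return d


def correlate(x, y) -> StatResult:
    """Pearson product-moment correlation with t-based p value and R^2."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("inputs must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(xa, ya)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * math.sqrt(df / (1.0 - r * r)) if abs(r) < 1 else math.inf
    return StatResult(
        estimate=float(r),
        statistic=float(t),
        df=df,
        p_value=float(p),
        method="pearson",
        extra={"r2": float(r * r), "n": n},
    )


def split_by_start_price(
    start_prices,
    values,
    boundary: float = 100.0,
    low_edge: float = -math.inf,
    high_edge: float = math.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition ``values`` into low/high start-price bins.

    Low bin: ``low_edge <= start < boundary``; high bin:
    ``boundary <= start <= high_edge`` (a start price exactly on the
    boundary goes to the high bin).  Warns when a bin comes out empty.
    """
    sp = np.asarray(start_prices, dtype=float)
    va = np.asarray(values, dtype=float)
    if sp.shape != va.shape:
        raise ValueError("start_prices and values must have equal shape")
    low = va[(sp >= low_edge) & (sp < boundary)]
    high = va[(sp >= boundary) & (sp <= high_edge)]
    if len(low) == 0 or len(high) == 0:
        warnings.warn("empty start-price bin", stacklevel=2)
    return low, high


def two_sample_t(a, b, compute_bf: bool = True) -> StatResult:
    """Independent-samples pooled-variance (Student) t test of a vs b.

    Degrees of freedom are ``n_a + n_b - 2``; the sign convention is
    ``mean(a) - mean(b)``.  A default JZS Bayes factor is attached unless
    ``compute_bf=False``.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(aa) == 0 and np.ptp(ba) == 0:
        raise ValueError("degenerate (zero-variance) samples")
    t, p = stats.ttest_ind(aa, ba, equal_var=True)
    df = len(aa) + len(ba) - 2
    bf = lnbf = None
    if compute_bf:
        bf, lnbf = jzs_bf_ttest(float(t), len(aa), len(ba))
    return StatResult(
        estimate=float(aa.mean() - ba.mean()),
        statistic=float(t),
        df=df,
        p_value=float(p),
        bf10=bf,
        log_bf10=lnbf,
        method="student_t_pooled",
        extra={"n1": len(aa), "n2": len(ba)},
    )


def _jzs_log_integrand(u: float, t2: float, neff: float, nu: float, scale: float):
    """Log integrand of the JZS marginal likelihood after g = exp(u).

    The effect-size prior is Cauchy(scale), equivalently an inverse-gamma
    (1/2, scale^2/2) mixture over the relative prior variance g.
    """
    g = math.exp(u)
    one_plus = 1.0 + neff * g
    return (
        -0.5 * math.log(one_plus)
        - 0.5 * (nu + 1.0) * math.log1p(t2 / (one_plus * nu))
        + math.log(scale)
        - 0.5 * math.log(2.0 * math.pi)
        - 1.5 * u
        - scale * scale / (2.0 * g)
        + u  # Jacobian of g = exp(u)
    )


def jzs_bf_ttest(
    t: float,
    n1: int,
    n2: int | None = None,
    scale: float = JZS_DEFAULT_SCALE,
) -> tuple[float, float]:
    """Default JZS Bayes factor BF10 for a t statistic, by quadrature.

    ``n2=None`` treats the statistic as one-sample/paired (effective sample
    size n1, df n1-1); otherwise independent two-sample (effective size
    ``n1*n2/(n1+n2)``, df ``n1+n2-2``).  Returns ``(bf10, ln_bf10)``; the
    result is invariant to the sign of t.  Computed in log space, so
    extreme statistics (ln BF ~ hundreds) do not overflow.
    """
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("need at least 2 observations per group")
    if scale <= 0:
        raise ValueError("prior scale must be positive")
    if n2 is None:
        neff, nu = float(n1), float(n1 - 1)
    else:
        neff, nu = n1 * n2 / (n1 + n2), float(n1 + n2 - 2)
    t2 = float(t) * float(t)

    res = optimize.minimize_scalar(
        lambda u: -_jzs_log_integrand(u, t2, neff, nu, scale),
        bounds=(-40.0, 40.0),
        method="bounded",
    )
    u_star, h_star = res.x, -res.fun
    val, _ = integrate.quad(
        lambda u: math.exp(_jzs_log_integrand(u, t2, neff, nu, scale) - h_star),
        u_star - 40.0,
        u_star + 40.0,
        limit=200,
    )
    if not np.isfinite(val) or val <= 0:
        raise ArithmeticError(
            f"JZS integration failed (t={t}, neff={neff}, value={val})"
        )
    ln_marginal = h_star + math.log(val)
    ln_null = -0.5 * (nu + 1.0) * math.log1p(t2 / nu)
    ln_bf = ln_marginal - ln_null
    return math.exp(ln_bf), ln_bf


def compare_paired_conditions(a, b, method: str = "auto") -> StatResult:
    """Paired comparison of two within-subject conditions.

    ``method='t'`` runs a paired t test, ``'wilcoxon'`` the signed-rank
    test, and ``'auto'`` picks by a Shapiro–Wilk normality check on the
    paired differences (alpha = 0.05).  The Shapiro p value is always
    reported in ``extra``.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if aa.shape != ba.shape or aa.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    diff = aa - ba
    if np.all(diff == 0):
        raise ValueError("all paired differences are zero (degenerate test)")
    shapiro_p = float(stats.shapiro(diff).pvalue) if len(diff) >= 3 else math.nan
    if method == "auto":
        method = "t" if (math.isnan(shapiro_p) or shapiro_p > 0.05) else "wilcoxon"
    if method == "t":
        t, p = stats.ttest_rel(aa, ba)
        bf, lnbf = jzs_bf_ttest(float(t), len(aa))
        return StatResult(
            estimate=float(diff.mean()),
            statistic=float(t),
            df=len(aa) - 1,
            p_value=float(p),
            bf10=bf,
            log_bf10=lnbf,
            method="paired_t",
            extra={"shapiro_p": shapiro_p, "n": len(aa)},
        )
    if method == "wilcoxon":
        res = stats.wilcoxon(aa, ba)
        return StatResult(
            estimate=float(np.median(diff)),
            statistic=float(res.statistic),
            df=None,
            p_value=float(res.pvalue),
            method="wilcoxon_signed_rank",
            extra={"shapiro_p": shapiro_p, "n": len(aa)},
        )
    raise ValueError(f"unknown method {method!r}")


class Ecdf:
    """Right-continuous empirical CDF: F(x) = #{v <= x} / n."""

    def __init__(self, values) -> None:
        va = np.asarray(values, dtype=float)
        if va.size < 1:
            raise ValueError("need at least one observation")
        self._sorted = np.sort(va)
        self.n = va.size

    def __call__(self, x):
        out = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right")
        out = out / self.n
        return out if out.ndim else float(out)

    @property
    def support(self) -> np.ndarray:
        return self._sorted


def ecdf(values) -> Ecdf:
    """Empirical CDF of a sample, evaluable at arbitrary points."""
    return Ecdf(values)


def repeated_measures_anova(data, dv: str, within, subject: str):
    """Thin wrapper over a standard repeated-measures ANOVA routine.

    Returns the underlying ANOVA table (with sphericity/Greenhouse–Geisser
    columns when applicable).  Routine plumbing, not a modelled quantity.
    """
    import pingouin  # deferred: slow import, only needed for this wrapper

    return pingouin.rm_anova(
        data=data, dv=dv, within=within, subject=subject, correction=True, detailed=True
    )
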