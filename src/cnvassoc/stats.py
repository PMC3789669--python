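"""Association statistics for 2x2 carrier tables and qPCR copy-number calling.

The one-sided Fisher test is computed with exact integer arithmetic over the
hypergeometric support, so its p-values are correctly rounded floats of the
exact rational tail probability.  The odds ratio reported alongside it is the
conditional maximum-likelihood estimate (cMLE): the noncentrality parameter
psi maximizing the Fisher noncentral hypergeometric likelihood of the observed
case-carrier count given the table margins.  This is the estimator printed by
standard Fisher-exact-test implementations and is slightly shrunk toward 1
relative to the cross-product (sample) odds ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import comb, lgamma
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .types import ContingencyTable, QpcrWell, SampleRecord, Status, ValidationError

__all__ = [
    "fisher_one_sided",
    "odds_ratio_cmle",
    "odds_ratio_sample",
    "odds_ratio_conditional_ci",
    "bonferroni",
    "logistic_cnvr",
    "LogisticResult",
    "SeparationError",
    "delta_delta_ct",
    "CopyNumberCall",
    "qpcr_concordance",
]


def _margins(t: ContingencyTable) -> tuple[int, int, int]:
    """Row totals (n1 cases, n2 controls) and first-column total k (carriers)."""
    n1 = t.a + t.b
    n2 = t.c + t.d
    k = t.a + t.c
    if n1 == 0 or n2 == 0 or (k == 0 and t.b + t.d == 0):
        raise ValidationError("degenerate margins: empty row or column")
    return n1, n2, k


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (case-enrichment) Fisher exact p-value, P(X >= a | margins).

    X follows the central hypergeometric distribution over the support
    [max(0, k - n2), min(n1, k)].  Computed exactly with big-integer
    binomial coefficients, then rounded once to float.
    """
    n1, n2, k = _margins(t)
    hi = min(n1, k)
    numerator = sum(comb(n1, x) * comb(n2, k - x) for x in range(t.a, hi + 1))
    denominator = comb(n1 + n2, k)
    return numerator / denominator


def odds_ratio_sample(t: ContingencyTable) -> float:
    """Cross-product ratio (a*d)/(b*c); +inf with a warning when b*c == 0."""
    if t.b * t.c == 0:
        warnings.warn("sample OR undefined (zero denominator); returning inf")
        return math.inf
    return (t.a * t.d) / (t.b * t.c)


def _log_weights(n1: int, n2: int, k: int) -> tuple[int, np.ndarray]:
    """Support lower bound and log C(n1,x) + C(n2,k-x) over the support."""
    lo = max(0, k - n2)
    hi = min(n1, k)
    xs = np.arange(lo, hi + 1)
    lw = np.array(
        [
            lgamma(n1 + 1) - lgamma(x + 1) - lgamma(n1 - x + 1)
            + lgamma(n2 + 1) - lgamma(k - x + 1) - lgamma(n2 - k + x + 1)
            for x in xs
        ]
    )
    return lo, lw


def _conditional_loglik(theta: float, a: int, lo: int, lw: np.ndarray) -> float:
    """Log-likelihood of psi = exp(theta) given observed a and the margins."""
    xs = np.arange(lo, lo + len(lw))
    terms = lw + xs * theta
    m = terms.max()
    return a * theta - (m + math.log(np.exp(terms - m).sum()))


def odds_ratio_cmle(t: ContingencyTable) -> float:
    """Conditional MLE of the odds ratio under the noncentral hypergeometric model.

    Returns +inf when the observed count sits at the top of the support
    (no control carriers alongside case carriers) and 0.0 at the bottom.
    The interior maximizer is found by golden-section search on log(psi);
    the likelihood is strictly log-concave in log(psi), so the optimum is
    unique.
    """
    n1, n2, k = _margins(t)
    lo_x, hi_x = max(0, k - n2), min(n1, k)
    if t.a > hi_x or t.a < lo_x:
        raise ValidationError("cell a outside the hypergeometric support")
    if lo_x == hi_x:  # single-point support: psi unidentifiable, conventionally 1
        return 1.0
    if t.a == hi_x:
        return math.inf
    if t.a == lo_x:
        return 0.0
    lo, lw = _log_weights(n1, n2, k)
    # start near the (continuity-corrected) sample log-OR
    theta0 = math.log(
        ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    )
    res = minimize_scalar(
        lambda th: -_conditional_loglik(th, t.a, lo, lw),
        bracket=(theta0 - 1.0, theta0 + 1.0),
        method="golden",
        options={"xtol": 1e-11},
    )
    return math.exp(res.x)


def _tail_ge(theta: float, a: int, lo: int, lw: np.ndarray) -> float:
    """P_psi(X >= a) under the noncentral hypergeometric with psi = exp(theta)."""
    xs = np.arange(lo, lo + len(lw))
    terms = lw + xs * theta
    m = terms.max()
    w = np.exp(terms - m)
    return float(w[xs >= a].sum() / w.sum())


def odds_ratio_conditional_ci(
    t: ContingencyTable, level: float = 0.95
) -> tuple[float, float]:
    """Exact conditional confidence interval for the odds ratio.

    Obtained by inverting the noncentral hypergeometric tail probabilities
    (the interval standard Fisher-test implementations report).  Open-ended
    at 0 / +inf when the observed count sits at the support boundary.
    """
    n1, n2, k = _margins(t)
    lo_x, hi_x = max(0, k - n2), min(n1, k)
    alpha = (1.0 - level) / 2.0
    lo, lw = _log_weights(n1, n2, k)
    span = (-60.0, 60.0)

    if t.a == lo_x:
        lower = 0.0
    else:
        lower = math.exp(brentq(lambda th: _tail_ge(th, t.a, lo, lw) - alpha, *span))
    if t.a == hi_x:
        upper = math.inf
    else:
        upper = math.exp(
            brentq(lambda th: (1.0 - _tail_ge(th, t.a + 1, lo, lw)) - alpha, *span)
        )
    return lower, upper


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, p * m)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 <= p <= 1:
        raise ValidationError("p outside [0, 1]")
    return min(1.0, p * m)


class SeparationError(RuntimeError):
    """The carrier indicator perfectly separates cases from controls."""


@dataclass
class LogisticResult:
    odds_ratio: float
    p_value: float
    coefficients: dict[str, float]
    converged: bool


def logistic_cnvr(
    carrier: Mapping[str, int],
    samples: Sequence[SampleRecord],
    covariates: Sequence[str] = ("age", "sex", "pc1", "pc2", "pc3"),
) -> LogisticResult:
    """Covariate-adjusted logistic model of case status on CNVR carrier state.

    ``covariates`` may name ``age``, ``sex`` and ``pc<i>`` (1-based principal
    component coordinates).  Returns the Wald test and exp(coefficient) for
    the carrier term.  Perfect separation raises :class:`SeparationError`
    rather than returning a divergent estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    rows = []
    y = []
    for s in samples:
        row = {"const": 1.0, "carrier": float(carrier.get(s.sample_id, 0))}
        for name in covariates:
            if name == "age":
                value = s.age
            elif name == "sex":
                value = None if s.sex is None else float(s.sex.value == "F")
            elif name.startswith("pc"):
                idx = int(name[2:]) - 1
                value = s.pcs[idx] if idx < len(s.pcs) else None
            else:
                raise ValidationError(f"unknown covariate {name!r}")
            if value is None:
                raise ValidationError(
                    f"sample {s.sample_id}: missing covariate {name!r}"
                )
            row[name] = float(value)
        rows.append(row)
        y.append(1.0 if s.status is Status.CASE else 0.0)

    import pandas as pd

    X = pd.DataFrame(rows)
    yv = np.asarray(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=100, tol=1e-10)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    coefs = dict(zip(X.columns, fit.params))
    if abs(coefs["carrier"]) > 15 or not np.isfinite(float(fit.bse["carrier"])):
        raise SeparationError("carrier coefficient diverged; perfect separation")
    return LogisticResult(
        odds_ratio=float(np.exp(coefs["carrier"])),
        p_value=float(fit.pvalues["carrier"]),
        coefficients={k: float(v) for k, v in coefs.items()},
        converged=bool(fit.mle_retvals.get("converged", True)),
    )


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    cn_estimate: float
    cn_call: int


def delta_delta_ct(
    wells: Iterable[QpcrWell], calibrator_id: str | None = None
) -> dict[str, CopyNumberCall]:
    """Relative-quantitation copy-number estimation from qPCR CT values.

    Per sample, dCT = mean(CT_target) - mean(CT_reference) over replicates.
    ddCT is taken against the calibrator sample's dCT when ``calibrator_id``
    is given (the calibrator is assumed diploid), otherwise against the
    cohort-mean dCT.  The estimate is ``2 * 2**(-ddCT)``; the integer call is
    the nearest integer.
    """
    by_sample: dict[str, list[QpcrWell]] = {}
    for w in wells:
        by_sample.setdefault(w.sample_id, []).append(w)
    if not by_sample:
        raise ValidationError("no qPCR wells provided")
    dct = {
        sid: float(np.mean([w.ct_target for w in ws]))
        - float(np.mean([w.ct_reference for w in ws]))
        for sid, ws in by_sample.items()
    }
    if calibrator_id is not None:
        if calibrator_id not in dct:
            raise ValidationError(f"calibrator sample {calibrator_id!r} absent")
        reference_dct = dct[calibrator_id]
    else:
        reference_dct = float(np.mean(list(dct.values())))
    out: dict[str, CopyNumberCall] = {}
    for sid, value in dct.items():
        ddct = value - reference_dct
        cn = 2.0 * 2.0 ** (-ddct)
        out[sid] = CopyNumberCall(sid, cn, int(round(cn)))
    return out


def qpcr_concordance(
    array_calls: Mapping[str, object], qpcr_calls: Mapping[str, object]
) -> float:
    """Fraction of shared samples with identical copy-number state."""
    shared = set(array_calls) & set(qpcr_calls)
    if not shared:
        raise ValidationError("no shared samples between array and qPCR calls")
    agree = sum(1 for sid in shared if array_calls[sid] == qpcr_calls[sid])
    return agree / len(shared)
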