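"""Model comparison: BIC, Bayes factors, and Jeffreys' evidence grades.

``BIC = q ln(n) - 2 Lhat`` (natural logarithm); for two models fit to the
same n decisions the Bayes factor of A over B is approximated by
``exp(-(BIC_A - BIC_B)/2)``.  A factor above 100 (or below 0.01) is
decisive on Jeffreys' scale; intermediate grades at 10^0.5 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["bic", "bayes_factor", "jeffreys_category", "compare", "ComparisonResult"]

#: (upper edge of the grade in Bayes-factor units, grade name); only the
#: decisive threshold at 100 is normative for the analyses here
JEFFREYS_GRADES = (
    (10.0**0.5, "barely worth mentioning"),
    (10.0, "substantial"),
    (10.0**1.5, "strong"),
    (100.0, "very strong"),
    (math.inf, "decisive"),
)


def bic(q: int, n: int, lhat: float) -> float:
    """Bayesian information criterion ``q*ln(n) - 2*lhat``."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if q < 0:
        raise ValidationError(f"q must be >= 0, got {q}")
    return q * math.log(n) - 2.0 * lhat


def bayes_factor(delta_bic: float) -> float:
    """Bayes factor ``exp(-delta_bic / 2)`` for a BIC difference."""
    return math.exp(-delta_bic / 2.0)


def jeffreys_category(bf: float) -> str:
    """Jeffreys' evidence grade for a Bayes factor of A over B, with the
    favored direction annotated."""
    if not bf > 0:
        raise ValidationError(f"Bayes factor must be > 0, got {bf!r}")
    if bf == 1.0:
        return "no preference"
    mag = bf if bf > 1 else 1.0 / bf
    direction = "A" if bf > 1 else "B"
    for edge, name in JEFFREYS_GRADES:
        if mag <= edge:
            return f"{name} in favor of {direction}"
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise model comparison on the same data set."""

    id_a: str
    id_b: str
    bic_a: float
    bic_b: float
    delta_bic: float
    bayes_factor: float
    jeffreys_label: str
    preferred: str | None

    def to_dict(self) -> dict:
        return {
            "model_a": self.id_a,
            "model_b": self.id_b,
            "bic_a": self.bic_a,
            "bic_b": self.bic_b,
            "delta_bic": self.delta_bic,
            "bayes_factor": self.bayes_factor,
            "jeffreys": self.jeffreys_label,
            "preferred": self.preferred,
        }


def compare(fit_a, fit_b, id_a: str = "A", id_b: str = "B") -> ComparisonResult:
    """Compare two fits of the *same* trial data by BIC.

    Requires matching decision counts n: BIC differences are only
    interpretable between models fit to the identical data set.
    """
    if fit_a.n != fit_b.n:
        raise ValidationError(
            f"cannot compare fits on different data (n={fit_a.n} vs n={fit_b.n})"
        )
    delta = fit_a.bic - fit_b.bic
    bf = bayes_factor(delta)
    if bf == 1.0:
        label = "no preference"
    else:
        mag = bf if bf > 1 else 1.0 / bf
        grade = next(name for edge, name in JEFFREYS_GRADES if mag <= edge)
        label = f"{grade} in favor of {id_a if bf > 1 else id_b}"
    preferred = None if delta == 0 else (id_a if delta < 0 else id_b)
    return ComparisonResult(id_a=id_a, id_b=id_b, bic_a=fit_a.bic, bic_b=fit_b.bic,
                            delta_bic=delta, bayes_factor=bf,
                            jeffreys_label=label, preferred=preferred)
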