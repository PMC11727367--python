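"""Bayes-factor model comparison and evidence classification.

BF10 quantifies the evidence the data provide for an alternative model over
a null model (the same model without the effect of interest).  The default
estimator is the BIC approximation,

    BF10 = exp((BIC_null - BIC_alt) / 2),

which is deterministic and respects reciprocity.  Evidence labels follow the
conventional graded bins on the H0 side (0.3-1 anecdotal, 0.1-0.3 moderate,
0.03-0.1 strong, 0.01-0.03 very strong, < 0.01 decisive) with the H1 side
defined as their exact reciprocals, so that classify(x) and classify(1/x)
are always mirror labels.  BF10 = 1 is no evidence either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from emomem.mixed_models import ModelError, ModelFit

#: Upper bin edges on the H0 side (exclusive), label order weak -> decisive.
_H0_BINS = [
    (0.3, "anecdotal H0"),
    (0.1, "moderate H0"),
    (0.03, "strong H0"),
    (0.01, "very strong H0"),
]


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    method: str
    evidence_label: str

    def to_dict(self) -> dict:
        return {"bf10": self.bf10, "method": self.method,
                "evidence_label": self.evidence_label}


def classify_evidence(bf10: float) -> str:
    """Graded evidence label for a Bayes factor.

    H0-side bins are half-open ``[low, high)``; the H1 side uses their
    reciprocal intervals ``(1/high, 1/low]``, which keeps the labeling
    exhaustive, mutually exclusive, and mirror-symmetric under ``x -> 1/x``.
    """
    if not (bf10 > 0) or math.isnan(bf10):
        raise ValueError(f"BF10 must be a positive real, got {bf10}")
    if bf10 == 1.0:
        return "none"
    if bf10 < 1.0:
        for edge, label in _H0_BINS:
            if bf10 >= edge:
                return label
        return "decisive H0"
    for edge, label in _H0_BINS:
        if bf10 <= 1.0 / edge:
            return label.replace("H0", "H1")
    return "decisive H1"


def bic_bayes_factor(fit_alt: ModelFit, fit_null: ModelFit,
                     method: str = "bic") -> BayesFactorResult:
    """BF10 for an alternative model against a nested null on the same rows.

    Only the BIC approximation is implemented; the ``method`` argument is
    the extension point for samplers with the same contract.
    """
    if method != "bic":
        raise NotImplementedError(f"BF method {method!r} not available")
    if fit_alt.n_obs != fit_null.n_obs:
        raise ModelError(
            f"fits use different rows ({fit_alt.n_obs} vs {fit_null.n_obs})"
        )
    bf10 = math.exp((fit_null.bic - fit_alt.bic) / 2.0)
    return BayesFactorResult(bf10=bf10, method="bic",
                             evidence_label=classify_evidence(bf10))
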