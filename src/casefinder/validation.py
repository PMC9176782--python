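"""Validity statistics for case-finding algorithms.

The module covers the full validation toolkit used when no gold standard
exists and different reference standards must be combined:

* case confirmation from a four-item manual-review form (malignant tumour,
  lung site, NSCLC morphology, primary origin — each yes/no/maybe), with a
  two-rater + referee adjudication rule;
* PPV and a treatment-based sensitivity indicator, as binomial proportions
  with Wilson score intervals;
* indirect sensitivity estimation from the algebraic identity
  ``SE = PPV x P / Pi`` linking PPV, observed incidence P and true
  incidence Pi — used when flagged counts exist but case-level truth does
  not.  Pi is taken as a fraction f of overall lung-cancer incidence;
  evaluating at f = 0.80 and f = 0.90 brackets the unknown NSCLC share and
  yields an SE range whose min/max ratio is exactly 8/9;
* Cohen's kappa for inter-rater agreement with Landis–Koch labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .registry_model import REVIEW_ITEMS, ReviewForm

__all__ = [
    "ValidityEstimate",
    "IncidenceInputs",
    "SERange",
    "KappaResult",
    "confirm_case",
    "adjudicate",
    "ppv",
    "se_indicator",
    "indirect_se",
    "se_range_by_year",
    "cohens_kappa",
    "landis_koch_label",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidityEstimate:
    """A proportion-valued validity index with its 95% CI.

    ``numerator``/``denominator`` are None for derived estimates (indirect
    SE) that are not a simple count ratio.
    """

    numerator: int | None
    denominator: int | None
    estimate: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError(
                f"inconsistent estimate/CI: {self.ci_low}, {self.estimate}, {self.ci_high}"
            )

    @property
    def percent(self) -> float:
        """Point estimate in percent, one decimal (reporting convention)."""
        return round(100.0 * self.estimate, 1)

    def __str__(self) -> str:
        return (
            f"{self.percent}% (95% CI {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}, "
            f"{self.method})"
        )


def _wilson(numerator: int, denominator: int) -> ValidityEstimate:
    estimate = numerator / denominator
    low, high = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    # guard against floating noise at boundary counts (e.g. 0/n)
    return ValidityEstimate(
        numerator=numerator,
        denominator=denominator,
        estimate=estimate,
        ci_low=min(float(low), estimate),
        ci_high=max(float(high), estimate),
        method="wilson",
    )


# ---------------------------------------------------------------------------
# Manual review
# ---------------------------------------------------------------------------


def confirm_case(form: ReviewForm) -> bool:
    """Confirmation rule: yes on the first three items, yes-or-maybe on origin.

    Pathology reports often cannot establish whether the lung tumour is
    primary, so an uncertain origin does not block confirmation; uncertainty
    on malignancy, site or morphology does.
    """
    return (
        form.malignancy == "yes"
        and form.lung_topography == "yes"
        and form.nsclc_morphology == "yes"
        and form.primary_origin in ("yes", "maybe")
    )


def adjudicate(form_a: ReviewForm, form_b: ReviewForm, referee: ReviewForm) -> ReviewForm:
    """Resolve two raters' forms item-wise; the referee decides disagreements."""
    if not (form_a.record_id == form_b.record_id == referee.record_id):
        raise ValueError(
            "adjudication requires forms for the same record, got "
            f"{form_a.record_id!r}, {form_b.record_id!r}, {referee.record_id!r}"
        )
    resolved = {
        item: getattr(form_a, item)
        if getattr(form_a, item) == getattr(form_b, item)
        else getattr(referee, item)
        for item in REVIEW_ITEMS
    }
    return ReviewForm(record_id=form_a.record_id, rater_id="adjudicated", **resolved)


# ---------------------------------------------------------------------------
# PPV and sensitivity
# ---------------------------------------------------------------------------


def ppv(n_confirmed: int, n_flagged: int) -> ValidityEstimate:
    """Positive predictive value: confirmed cases among algorithm-flagged cases."""
    if n_flagged <= 0:
        raise ValueError("PPV denominator must be positive")
    if not 0 <= n_confirmed <= n_flagged:
        raise ValueError("need 0 <= n_confirmed <= n_flagged")
    return _wilson(n_confirmed, n_flagged)


def se_indicator(n_treated_identified: int, n_treated_total: int) -> ValidityEstimate:
    """Sensitivity indicator: algorithm-identified share of treated patients.

    Both counts are patient-level (deduplicated).  The reference standard is
    the hospital-pharmacy table of patients treated with NSCLC-indicated
    drugs — an imperfect but case-level standard.
    """
    if n_treated_total <= 0:
        raise ValueError("SE indicator denominator must be positive")
    if not 0 <= n_treated_identified <= n_treated_total:
        raise ValueError("need 0 <= identified <= total")
    return _wilson(n_treated_identified, n_treated_total)


@dataclass(frozen=True)
class IncidenceInputs:
    """Aggregate inputs of the indirect SE identity.

    observed_incidence
        P: algorithm-flagged incident cases per population per year.
    lung_cancer_incidence
        L: overall lung-cancer incidence from the cancer registry.
    nsclc_fraction
        f: assumed NSCLC share of lung cancers; true incidence Pi = f * L.
    """

    observed_incidence: float
    lung_cancer_incidence: float
    nsclc_fraction: float

    def __post_init__(self) -> None:
        for name in ("observed_incidence", "lung_cancer_incidence", "nsclc_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")

    @property
    def true_incidence(self) -> float:
        return self.nsclc_fraction * self.lung_cancer_incidence


def indirect_se(
    ppv_est: float, inputs: IncidenceInputs, population: int | None = None
) -> ValidityEstimate:
    """Indirect sensitivity: SE = PPV x P / Pi.

    With a population size, the flagged count P*N is treated as binomial and
    its Wilson interval is transformed through the identity with PPV and Pi
    held fixed (an approximation, labeled in ``method``); without one, the
    CI degenerates to the point estimate.  Estimates above 1 (inconsistent
    inputs) are capped with a warning.
    """
    if not 0.0 <= ppv_est <= 1.0:
        raise ValueError("ppv_est must lie in [0, 1]")
    pi = inputs.true_incidence
    if pi <= 0.0:
        raise ValueError("true incidence must be positive")
    scale = ppv_est / pi
    point = scale * inputs.observed_incidence
    if point > 1.0:
        warnings.warn(
            f"indirect SE {point:.3f} exceeds 1 (PPV*P > Pi); capping at 1", stacklevel=2
        )
    if population is not None:
        count = int(round(inputs.observed_incidence * population))
        low, high = proportion_confint(count, population, alpha=0.05, method="wilson")
        ci_low, ci_high = scale * float(low), scale * float(high)
        method = "indirect (wilson on flagged count)"
    else:
        ci_low = ci_high = point
        method = "indirect (point only)"
    cap = lambda x: min(max(x, 0.0), 1.0)  # noqa: E731
    return ValidityEstimate(
        numerator=None,
        denominator=None,
        estimate=cap(point),
        ci_low=cap(min(ci_low, point)),
        ci_high=cap(max(ci_high, point)),
        method=method,
    )


@dataclass(frozen=True)
class SERange:
    """Min/max indirect SE for one year (f = 0.90 and f = 0.80 assumptions)."""

    year: int
    se_min: ValidityEstimate
    se_max: ValidityEstimate


def se_range_by_year(
    ppv_est: float,
    annual_counts: Mapping[int, int],
    population_by_year: Mapping[int, int],
    lung_cancer_incidence: float,
    f_low: float = 0.80,
    f_high: float = 0.90,
) -> list[SERange]:
    """Per-year SE range bracketing the unknown NSCLC share of lung cancers.

    True incidence is held constant over calendar time at the supplied
    reference lung-cancer incidence (typically the most recent cancer-
    registry estimate).  The larger assumed share (f_high) gives the lower
    SE bound, so se_min/se_max = f_low/f_high = 8/9 at the defaults.
    """
    out: list[SERange] = []
    for year in sorted(annual_counts):
        if year not in population_by_year:
            raise ValueError(f"no population count for year {year}")
        population = population_by_year[year]
        count = annual_counts[year]
        if count == 0:
            zero = ValidityEstimate(None, None, 0.0, 0.0, 0.0, "indirect (zero cases)")
            out.append(SERange(year=year, se_min=zero, se_max=zero))
            continue
        p = count / population
        se_max = indirect_se(
            ppv_est,
            IncidenceInputs(p, lung_cancer_incidence, f_low),
            population=population,
        )
        se_min = indirect_se(
            ppv_est,
            IncidenceInputs(p, lung_cancer_incidence, f_high),
            population=population,
        )
        out.append(SERange(year=year, se_min=se_min, se_max=se_max))
    return out


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------


def landis_koch_label(kappa: float | None) -> str:
    if kappa is None:
        return "undefined"
    if kappa <= 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    observed_agreement: float
    expected_agreement: float
    label: str


def cohens_kappa(ratings_a: Sequence[str], ratings_b: Sequence[str]) -> KappaResult:
    """Unweighted Cohen's kappa between two raters' categorical ratings.

    kappa = (po - pe) / (1 - pe) with po the observed and pe the chance
    agreement from the raters' marginals.  When both raters are constant and
    identical, pe = 1 and kappa is undefined (returned as None with a
    warning), not 1.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating sequences differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if len(ratings_a) == 0:
        raise ValueError("rating sequences must be non-empty")
    a = np.asarray(ratings_a, dtype=object)
    b = np.asarray(ratings_b, dtype=object)
    categories = sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    n = table.sum()
    po = float(np.trace(table) / n)
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        warnings.warn("both raters are constant and identical; kappa undefined", stacklevel=2)
        return KappaResult(kappa=None, observed_agreement=po, expected_agreement=1.0,
                           label="undefined")
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(
        kappa=kappa, observed_agreement=po, expected_agreement=pe,
        label=landis_koch_label(kappa),
    )
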