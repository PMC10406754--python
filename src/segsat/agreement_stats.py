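"""Cohort-level agreement statistics for segmentation volumetry.

Three analyses, matching how segmentation studies report volumetric
concordance of a final model against the reference standard:

* ordinary least-squares regression of predicted on reference volumes, with
  R² as the squared Pearson correlation;
* Bland–Altman analysis of per-case *percent* volume differences,
  100·(pred − ref)/denominator, with bias (mean), sample SD, and limits of
  agreement bias ± 1.96·SD.  The denominator is configurable: ``reference``
  (relative error against ground truth, the default) or ``mean`` (the
  classical Bland–Altman choice);
* two-sided paired Student's t-tests of per-case Dice between dataset sizes,
  with significance coded ***p<=0.001, **p<=0.01, *p<=0.05.  No
  multiple-testing correction is applied across adjacent-size comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "PairedTestResult",
    "volume_regression",
    "bland_altman_percent",
    "paired_t_test",
    "adjacent_size_tests",
    "significance_stars",
]


@dataclass(frozen=True)
class AgreementReport:
    """Volume-agreement summary: OLS regression + Bland–Altman percent diff."""

    slope: float
    intercept: float
    r_squared: float
    ba_bias_pct: float
    ba_sd_pct: float
    ba_loa_low_pct: float
    ba_loa_high_pct: float
    n_cases: int
    denominator_rule: str = "reference"
    excluded_cases: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "ba_bias_pct": self.ba_bias_pct,
            "ba_sd_pct": self.ba_sd_pct,
            "ba_loa_low_pct": self.ba_loa_low_pct,
            "ba_loa_high_pct": self.ba_loa_high_pct,
            "n_cases": self.n_cases,
            "denominator_rule": self.denominator_rule,
            "excluded_cases": list(self.excluded_cases),
        }


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test between matched per-case score vectors."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    significance_stars: str
    degenerate: str | None = None  # 'all_zero_diff' | 'zero_variance_diff'


def significance_stars(p: float) -> str:
    """Star coding: *** p<=0.001, ** p<=0.01, * p<=0.05, else empty."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def volume_regression(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS of predicted on reference volume: (slope, intercept, r_squared).

    Needs >= 3 pairs with non-constant reference values.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (ref, pred) tuples")
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs for regression, got {len(pairs)}")
    ref, pred = pairs[:, 0], pairs[:, 1]
    if np.ptp(ref) == 0:
        raise ValueError("reference volumes are all equal; regression undefined")
    result = stats.linregress(ref, pred)
    return float(result.slope), float(result.intercept), float(result.rvalue**2)


def bland_altman_percent(
    pairs: Sequence[tuple[float, float]],
    denominator_rule: Literal["reference", "mean"] = "reference",
    case_ids: Sequence[str] | None = None,
) -> AgreementReport:
    """Bland–Altman analysis of percent volume differences.

    Per-case percent difference is 100·(pred − ref)/denominator where the
    denominator is the reference volume (default) or the pair mean.  Cases
    with a zero denominator are excluded and listed in the report.  Needs
    >= 2 usable pairs.  The regression fields of the returned report are
    filled when >= 3 usable pairs with non-constant reference exist, else NaN.
    """
    if denominator_rule not in ("reference", "mean"):
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    pairs = np.asarray(pairs, dtype=float)
    if case_ids is None:
        case_ids = [str(i) for i in range(len(pairs))]
    ref, pred = pairs[:, 0], pairs[:, 1]
    denom = ref if denominator_rule == "reference" else 0.5 * (ref + pred)
    usable = denom != 0
    excluded = tuple(cid for cid, ok in zip(case_ids, usable) if not ok)
    ref_u, pred_u, denom_u = ref[usable], pred[usable], denom[usable]
    if len(ref_u) < 2:
        raise ValueError("need >= 2 pairs with nonzero denominator")
    pct = 100.0 * (pred_u - ref_u) / denom_u
    bias = float(np.mean(pct))
    sd = float(np.std(pct, ddof=1))
    try:
        slope, intercept, r2 = volume_regression(list(zip(ref_u, pred_u)))
    except ValueError:
        slope = intercept = r2 = float("nan")
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        ba_bias_pct=bias,
        ba_sd_pct=sd,
        ba_loa_low_pct=bias - 1.96 * sd,
        ba_loa_high_pct=bias + 1.96 * sd,
        n_cases=int(usable.sum()),
        denominator_rule=denominator_rule,
        excluded_cases=excluded,
    )


def paired_t_test(
    dice_a: Sequence[float], dice_b: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired Student's t-test on matched per-case scores.

    Degenerate inputs are flagged rather than erroring: identical vectors
    give t=0, p=1 (``all_zero_diff``); a constant nonzero difference gives a
    sign-correct infinite t with p=0 (``zero_variance_diff``).
    """
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    dof = n - 1
    if np.all(diff == 0):
        return PairedTestResult(0.0, dof, 1.0, n, "", degenerate="all_zero_diff")
    if np.std(diff, ddof=1) == 0:
        t = float(np.inf if diff.mean() > 0 else -np.inf)
        return PairedTestResult(
            t, dof, 0.0, n, "***", degenerate="zero_variance_diff"
        )
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=dof,
        p_value=p,
        n_pairs=n,
        significance_stars=significance_stars(p),
    )


def adjacent_size_tests(
    dice_by_size: Mapping[int, Mapping[str, float]],
) -> list[tuple[int, int, PairedTestResult]]:
    """Paired t-tests between consecutive dataset sizes, ascending.

    ``dice_by_size`` maps each dataset size to {case_id: dice}; every size
    must cover the same test cases.  Returns (size_a, size_b, result)
    triples for each adjacent pair.
    """
    sizes = sorted(dice_by_size)
    if len(sizes) < 2:
        raise ValueError("need >= 2 dataset sizes")
    case_sets = {s: frozenset(dice_by_size[s]) for s in sizes}
    first = case_sets[sizes[0]]
    for s in sizes[1:]:
        if case_sets[s] != first:
            extra = sorted((case_sets[s] ^ first))[:5]
            raise ValueError(
                f"case sets differ between sizes {sizes[0]} and {s} "
                f"(e.g. {extra})"
            )
    order = sorted(first)
    results = []
    for s_a, s_b in zip(sizes, sizes[1:]):
        a = [dice_by_size[s_a][c] for c in order]
        b = [dice_by_size[s_b][c] for c in order]
        results.append((s_a, s_b, paired_t_test(a, b)))
    return results
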