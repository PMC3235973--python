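"""Positive predictive value with Wilson score confidence intervals.

The PPV of the claims case definition is the proportion of adjudicable
flagged cases that the chart-review gold standard confirms, x/n. Interval
estimates use Wilson's score interval — the inversion of the normal
approximation to the score test — which stays inside [0, 1] and behaves
well at proportions near 0 or 1 and at small n, the relevant regime here:

    (p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

with z the exact normal quantile at (1+conf)/2 and no continuity
correction. Results can be stratified by exposure group, age band,
gender, and ADHD diagnosis, and rendered as a fixed-width report plus a
machine-readable CSV. Displayed percentages are rounded half-up to one
decimal; full precision is retained internally.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
from scipy.stats import norm

__all__ = [
    "StratumResult",
    "DEFAULT_STRATA",
    "wilson_interval",
    "clopper_pearson_interval",
    "round_half_up",
    "compute_ppv",
    "stratified_ppv",
    "render_report",
    "report_frame",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 96.05 → 96.1), matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def wilson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Returns (lo, hi) on the proportion scale, lo ≤ x/n ≤ hi. Closed form,
    exact normal quantile, no continuity correction. Raises ``ValueError``
    for n = 0 or out-of-range arguments.
    """
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not 0 <= x <= n:
        raise ValueError("wilson_interval requires 0 <= x <= n")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    z = norm.ppf((1.0 + conf) / 2.0)
    p = x / n
    z2n = z * z / n
    denom = 1.0 + z2n
    center = (p + z2n / 2.0) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # endpoints are exact at x = 0 and x = n (center ∓ half collapses there)
    lo = 0.0 if x == 0 else max(0.0, float(center - half))
    hi = 1.0 if x == n else min(1.0, float(center + half))
    return lo, hi


def clopper_pearson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) interval, provided for comparison only."""
    from scipy.stats import beta

    if n < 1:
        raise ValueError("clopper_pearson_interval requires n >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else beta.ppf(alpha / 2.0, x, n - x + 1)
    hi = 1.0 if x == n else beta.ppf(1.0 - alpha / 2.0, x + 1, n - x)
    return float(lo), float(hi)


@dataclasses.dataclass
class StratumResult:
    """PPV and Wilson CI for one stratum (or the overall sample).

    ``ppv``, ``ci_lo``, ``ci_hi`` are full-precision proportions; the
    ``*_percent`` fields are the display values, rounded half-up to one
    decimal on the percent scale.
    """

    rule: str
    label: str
    n: int
    x: int
    conf: float = 0.95
    ppv: float = dataclasses.field(init=False)
    ci_lo: float = dataclasses.field(init=False)
    ci_hi: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError("need 0 <= x <= n")
        self.ppv = self.x / self.n
        self.ci_lo, self.ci_hi = wilson_interval(self.x, self.n, self.conf)

    @property
    def ppv_percent(self) -> float:
        return round_half_up(100.0 * self.ppv)

    @property
    def ci_lo_percent(self) -> float:
        return round_half_up(100.0 * self.ci_lo)

    @property
    def ci_hi_percent(self) -> float:
        return round_half_up(100.0 * self.ci_hi)


def compute_ppv(
    adjudicated: pd.DataFrame,
    rule: str = "overall",
    label: str = "overall",
    conf: float = 0.95,
) -> StratumResult:
    """Overall PPV over an adjudicated-results frame (``confirmed`` column)."""
    if len(adjudicated) == 0:
        raise ValueError("no adjudicated cases: PPV undefined")
    n = int(len(adjudicated))
    x = int(adjudicated["confirmed"].sum())
    return StratumResult(rule=rule, label=label, n=n, x=x, conf=conf)


def _age_band(row: pd.Series) -> str:
    return "upper (11-24 years)" if int(row["age_years"]) >= 11 else "lower (<=10 years)"


#: Default stratification rules, each an exhaustive, disjoint partition.
DEFAULT_STRATA: Mapping[str, Callable[[pd.Series], str]] = {
    "exposure": lambda row: (
        "antipsychotic" if row["exposure_group"] == "antipsychotic" else "control"
    ),
    "age": _age_band,
    "gender": lambda row: str(row["gender"]),
    "adhd": lambda row: "yes" if bool(row["adhd_dx"]) else "no",
}

_STRATA_ATTRIBUTES = {
    "exposure": "exposure_group",
    "age": "age_years",
    "gender": "gender",
    "adhd": "adhd_dx",
}


def stratified_ppv(
    adjudicated: pd.DataFrame,
    strata: Mapping[str, Callable[[pd.Series], str]] | None = None,
    conf: float = 0.95,
) -> list[StratumResult]:
    """One :class:`StratumResult` per level per stratification rule.

    Raises ``ValueError`` naming the offending record when a required
    stratum attribute is missing.
    """
    strata = DEFAULT_STRATA if strata is None else strata
    results: list[StratumResult] = []
    for rule, labeler in strata.items():
        attr = _STRATA_ATTRIBUTES.get(rule)
        if attr is not None and attr in adjudicated.columns:
            missing = adjudicated[attr].isna()
            if missing.any():
                pid = adjudicated.loc[missing, "person_id"].iloc[0]
                raise ValueError(
                    f"record {pid!r} is missing stratum attribute {attr!r}"
                )
        labels = adjudicated.apply(labeler, axis=1)
        for label in sorted(labels.unique()):
            sub = adjudicated[labels == label]
            results.append(
                StratumResult(
                    rule=rule,
                    label=label,
                    n=int(len(sub)),
                    x=int(sub["confirmed"].sum()),
                    conf=conf,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_frame(results: Iterable[StratumResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "rule": r.rule,
                "stratum": r.label,
                "n": r.n,
                "confirmed": r.x,
                "ppv_percent": r.ppv_percent,
                "ci_lo_percent": r.ci_lo_percent,
                "ci_hi_percent": r.ci_hi_percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rule",
            "stratum",
            "n",
            "confirmed",
            "ppv_percent",
            "ci_lo_percent",
            "ci_hi_percent",
        ],
    )


def render_report(
    overall: StratumResult, strata_results: Iterable[StratumResult] = ()
) -> str:
    """Fixed-width validation report, one row per stratum."""
    lines = []
    header = f"{'Stratum':34s} {'x/n':>7s} {'PPV (%)':>8s}  {'95% CI':>15s}"
    lines.append("Positive predictive value of the computer case definition")
    lines.append(header)
    lines.append("-" * len(header))

    def fmt(r: StratumResult, indent: str = "") -> str:
        ci = f"{r.ci_lo_percent:.1f} to {r.ci_hi_percent:.1f}"
        return (
            f"{indent + r.label:34s} {f'{r.x}/{r.n}':>7s} "
            f"{r.ppv_percent:8.1f}  {ci:>15s}"
        )

    lines.append(fmt(dataclasses.replace(overall, label="overall")))
    current_rule = None
    for r in strata_results:
        if r.rule != current_rule:
            current_rule = r.rule
            lines.append(f"by {current_rule}")
        lines.append(fmt(r, indent="  "))
    return "\n".join(lines) + "\n"


def write_report(
    overall: StratumResult,
    strata_results: Iterable[StratumResult],
    text_path: str | Path,
    csv_path: str | Path,
) -> None:
    strata_results = list(strata_results)
    Path(text_path).write_text(render_report(overall, strata_results))
    report_frame([overall, *strata_results]).to_csv(csv_path, index=False)
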