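"""Stratified 2x2 contingency statistics for region x mutation-type tables.

Each antibody clone contributes one stratum: a 2x2 table of replacement vs
silent mutation counts in CDR vs FR.  Stratifying by antibody, rather than
pooling, prevents Simpson's-paradox bias.  Three classical statistics are
computed:

* the **Mantel-Haenszel common odds ratio**, a weighted average of the
  per-stratum odds ratios,

      OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i);

* the **Cochran-Mantel-Haenszel chi-square test** of association (df = 1),
  comparing sum_i a_i with its hypergeometric expectation under the null of
  no association within any stratum;

* the **Breslow-Day chi-square test** of odds-ratio homogeneity (df = K-1),
  which fits, per stratum, the expected a-cell consistent with the common
  OR and the stratum margins, and sums squared standardized deviations.

Cell roles follow the table orientation (rows CDR/FR, columns R/S):
a = CDR R, b = CDR S, c = FR R, d = FR S, so OR > 1 means replacement
mutations are enriched in the CDRs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from scipy import stats as sps

STRATA_COLUMNS = ["label", "cdr_r", "cdr_s", "fr_r", "fr_s"]


class StratifiedStatsError(ValueError):
    pass


@dataclass(frozen=True)
class Stratum2x2:
    """One antibody's 2x2 table: (CDR R, CDR S, FR R, FR S)."""

    label: str
    a: int  # CDR replacement
    b: int  # CDR silent
    c: int  # FR replacement
    d: int  # FR silent

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, int)) or x < 0 for x in cells):
            raise StratifiedStatsError(
                f"stratum {self.label!r}: cells must be non-negative integers, got {cells}"
            )
        if sum(cells) == 0:
            raise StratifiedStatsError(f"stratum {self.label!r}: empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self, zero_policy: str = "raw") -> float:
        """Per-stratum OR (a*d)/(b*c).

        ``zero_policy='raw'`` lets the arithmetic speak (+inf, 0 or NaN on
        zero cells); ``'haldane'`` adds 0.5 to every cell first.
        """
        a, b, c, d = self.a, self.b, self.c, self.d
        if zero_policy == "haldane":
            return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        if zero_policy != "raw":
            raise StratifiedStatsError(f"unknown zero_policy {zero_policy!r}")
        num, den = a * d, b * c
        if den == 0:
            return math.nan if num == 0 else math.inf
        return num / den


class StratifiedTable:
    """K >= 1 uniquely-labelled strata of 2x2 counts."""

    def __init__(self, strata: Iterable[Stratum2x2]):
        self.strata = tuple(strata)
        if not self.strata:
            raise StratifiedStatsError("need at least one stratum")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise StratifiedStatsError(f"duplicate stratum labels in {labels}")

    def __len__(self) -> int:
        return len(self.strata)

    def __iter__(self):
        return iter(self.strata)

    @classmethod
    def from_mutation_table(cls, table: pd.DataFrame) -> "StratifiedTable":
        """Build strata from a per-clone mutation table's Total columns."""
        return cls(
            Stratum2x2(
                str(clone),
                int(row["TotalCDR_R"]),
                int(row["TotalCDR_S"]),
                int(row["TotalFR_R"]),
                int(row["TotalFR_S"]),
            )
            for clone, row in table.iterrows()
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "StratifiedTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(STRATA_COLUMNS) - set(df.columns)
        if missing:
            raise StratifiedStatsError(f"strata TSV missing columns {sorted(missing)}")
        return cls(
            Stratum2x2(str(r.label), int(r.cdr_r), int(r.cdr_s), int(r.fr_r), int(r.fr_s))
            for r in df.itertuples()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.label, s.a, s.b, s.c, s.d) for s in self.strata],
            columns=STRATA_COLUMNS,
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    estimate: Optional[float] = None
    warnings: tuple[str, ...] = field(default=())

    def __str__(self) -> str:  # paper-style 3-decimal reporting
        est = f", estimate = {self.estimate:.3g}" if self.estimate is not None else ""
        return (
            f"{self.method}: chi-square = {self.statistic:.2f}, "
            f"df = {self.df}, p = {self.p_value:.3f}{est}"
        )


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the chi-square distribution."""
    if df < 1:
        raise StratifiedStatsError(f"df must be >= 1, got {df}")
    if x < 0:
        raise StratifiedStatsError(f"chi-square statistic must be >= 0, got {x}")
    return float(sps.chi2.sf(x, df))


def mh_common_or(table: StratifiedTable) -> float:
    """Mantel-Haenszel common odds ratio across strata.

    Zero cells are handled natively: their cross-product terms simply
    vanish.  An all-zero denominator yields +inf with a warning.
    """
    num = sum(s.a * s.d / s.n for s in table)
    den = sum(s.b * s.c / s.n for s in table)
    if den == 0:
        warnings.warn("MH common OR denominator is 0; estimate is +inf", stacklevel=2)
        return math.inf
    return num / den


def cmh_test(table: StratifiedTable, continuity_correction: bool = False) -> TestResult:
    """Cochran-Mantel-Haenszel chi-square test of association (df = 1)."""
    obs = exp = var = 0.0
    notes = []
    for s in table:
        r1, r2 = s.a + s.b, s.c + s.d
        c1, c2 = s.a + s.c, s.b + s.d
        if min(r1, r2, c1, c2) == 0 or s.n < 2:
            notes.append(f"stratum {s.label!r} has a zero margin; skipped")
            continue
        obs += s.a
        exp += r1 * c1 / s.n
        var += r1 * r2 * c1 * c2 / (s.n**2 * (s.n - 1))
    if notes:
        warnings.warn("; ".join(notes), stacklevel=2)
    if var == 0:
        return TestResult(0.0, 1, 1.0, "CMH chi-square", mh_common_or(table), tuple(notes))
    dev = abs(obs - exp)
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    stat = dev**2 / var
    return TestResult(
        stat, 1, chi2_upper_tail(stat, 1), "CMH chi-square",
        estimate=mh_common_or(table), warnings=tuple(notes),
    )


def _fitted_a_cell(s: Stratum2x2, psi: float) -> float:
    """Expected a-cell under common OR ``psi`` given the stratum margins.

    Solves a*(n-r1-c1+a) = psi*(r1-a)*(c1-a) for the admissible root
    max(0, r1+c1-n) <= a <= min(r1, c1).
    """
    r1, c1, n = s.a + s.b, s.a + s.c, s.n
    lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)
    if psi == 1.0:
        return r1 * c1 / n
    # (1-psi) a^2 + [n - r1 - c1 + psi (r1 + c1)] a - psi r1 c1 = 0
    A = 1.0 - psi
    B = (n - r1 - c1) + psi * (r1 + c1)
    C = -psi * r1 * c1
    disc = B * B - 4 * A * C
    if disc < 0:
        raise StratifiedStatsError(
            f"stratum {s.label!r}: no real root for the fitted cell (margins inconsistent)"
        )
    sq = math.sqrt(disc)
    for root in ((-B + sq) / (2 * A), (-B - sq) / (2 * A)):
        if lo - 1e-9 <= root <= hi + 1e-9:
            return min(max(root, lo), hi)
    raise StratifiedStatsError(
        f"stratum {s.label!r}: no admissible root in [{lo}, {hi}]"
    )


def breslow_day_test(
    table: StratifiedTable,
    tarone_adjustment: bool = False,
    common_or: Optional[float] = None,
) -> TestResult:
    """Breslow-Day chi-square test of odds-ratio homogeneity (df = K-1).

    Uses the MH common OR as the homogeneity null unless ``common_or``
    overrides it.  ``tarone_adjustment`` subtracts the squared total
    deviation term (Tarone's correction for using the MH estimator).
    Strata with a zero margin carry no information about the OR and are
    skipped with a warning, reducing the degrees of freedom.
    """
    if len(table) < 2:
        raise StratifiedStatsError("Breslow-Day test needs at least 2 strata")
    psi = mh_common_or(table) if common_or is None else common_or
    if not (math.isfinite(psi) and psi > 0):
        raise StratifiedStatsError(
            f"common OR must be finite and positive for the homogeneity null, got {psi}"
        )
    stat = 0.0
    sum_dev = 0.0
    sum_var = 0.0
    used = 0
    notes = []
    for s in table:
        r1, c1 = s.a + s.b, s.a + s.c
        if min(r1, c1, s.n - r1, s.n - c1) == 0:
            notes.append(f"stratum {s.label!r} has a zero margin; skipped")
            continue
        a_fit = _fitted_a_cell(s, psi)
        b_fit, c_fit = r1 - a_fit, c1 - a_fit
        d_fit = s.n - r1 - c1 + a_fit
        var = 1.0 / (1.0 / a_fit + 1.0 / b_fit + 1.0 / c_fit + 1.0 / d_fit)
        stat += (s.a - a_fit) ** 2 / var
        sum_dev += s.a - a_fit
        sum_var += var
        used += 1
    if notes:
        warnings.warn("; ".join(notes), stacklevel=2)
    if used < 2:
        raise StratifiedStatsError("fewer than 2 informative strata for Breslow-Day")
    if tarone_adjustment:
        stat -= sum_dev**2 / sum_var
    df = used - 1
    method = "Breslow-Day" + (" (Tarone)" if tarone_adjustment else "")
    return TestResult(stat, df, chi2_upper_tail(stat, df), method,
                      estimate=psi, warnings=tuple(notes))


def analyze(
    table: StratifiedTable,
    continuity_correction: bool = False,
    tarone_adjustment: bool = False,
) -> dict:
    """Full report: per-stratum ORs, common OR, CMH and Breslow-Day tests."""
    report: dict = {
        "strata": [
            {
                "label": s.label,
                "cdr_r": s.a,
                "cdr_s": s.b,
                "fr_r": s.c,
                "fr_s": s.d,
                "odds_ratio": s.odds_ratio("raw"),
                "odds_ratio_haldane": s.odds_ratio("haldane"),
            }
            for s in table
        ],
        "mh_common_or": mh_common_or(table),
    }
    cmh = cmh_test(table, continuity_correction)
    report["cmh"] = {
        "statistic": cmh.statistic,
        "df": cmh.df,
        "p_value": cmh.p_value,
        "continuity_correction": continuity_correction,
    }
    if len(table) >= 2:
        try:
            bd = breslow_day_test(table, tarone_adjustment)
            report["breslow_day"] = {
                "statistic": bd.statistic,
                "df": bd.df,
                "p_value": bd.p_value,
                "tarone_adjustment": tarone_adjustment,
            }
        except StratifiedStatsError as exc:
            report["breslow_day"] = {"skipped": str(exc)}
    else:
        report["breslow_day"] = {"skipped": "needs at least 2 strata"}
    return report
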