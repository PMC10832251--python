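"""Population-level kdr statistics: allele frequencies and HWE screening.

Per sampling location, the input is the RR/RS/SS genotype tally from PASA (or
sequencing).  This module computes kdr allele counts and frequencies, the
fixed-denominator percentage used in the packaged survey table, a
Hardy-Weinberg equilibrium chi-square test (1 df, no continuity correction),
and per-survey aggregates.

Two percentage conventions coexist on purpose:

* ``allele_stats`` uses the statistically standard 2N denominator;
* ``paper_percent`` divides the kdr allele count by a *fixed* number of allele
  copies (default 32, i.e. a nominal 16 flies per site) — the convention the
  packaged survey table was published with, kept so the printed column can be
  reproduced row for row.  Summaries default to 2N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from scipy.stats import chi2 as chi2_dist


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: half-up (the usual hand-calculation convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-location RR/RS/SS tallies."""

    location: str
    n_RR: int
    n_RS: int
    n_SS: int

    def __post_init__(self) -> None:
        for fld in ("n_RR", "n_RS", "n_SS"):
            v = getattr(self, fld)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{fld} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.n_RR + self.n_RS + self.n_SS


@dataclass(frozen=True)
class AlleleStats:
    kdr_count: int
    sus_count: int
    frequency: float


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p_value: Optional[float]  # None iff monomorphic
    df: int
    expected_RR: float
    expected_RS: float
    expected_SS: float
    monomorphic: bool


@dataclass(frozen=True)
class SurveyAggregates:
    total: GenotypeCounts
    pct_RR: float                 # raw percentage of RR insects over all insects
    pct_RS: float
    n_locations: int
    n_locations_with_kdr: int
    n_locations_with_RR: int
    pct_locations_with_RR: float  # rounded, 1 dp
    n_locations_deviating_hwe: int
    alpha: float


@dataclass(frozen=True)
class PopulationSummary:
    per_location: pd.DataFrame
    aggregates: SurveyAggregates


def allele_stats(counts: GenotypeCounts) -> AlleleStats:
    """kdr/sus allele counts and the 2N-denominator kdr allele frequency."""
    if counts.N == 0:
        raise ValueError(f"{counts.location}: N must be >= 1")
    kdr = 2 * counts.n_RR + counts.n_RS
    sus = 2 * counts.n_SS + counts.n_RS
    return AlleleStats(kdr_count=kdr, sus_count=sus, frequency=kdr / (2 * counts.N))


def paper_percent(counts: GenotypeCounts, denominator_alleles: int = 32) -> float:
    """kdr allele count over a fixed allele-copy denominator, in %, 1 dp half-up."""
    if denominator_alleles <= 0:
        raise ValueError("denominator_alleles must be positive")
    kdr = 2 * counts.n_RR + counts.n_RS
    return round_half_up(100.0 * kdr / denominator_alleles, 1)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Hardy-Weinberg chi-square test for one biallelic locus.

    With allele frequency p estimated from the sample and q = 1 - p, expected
    genotype counts are N*p^2, 2Npq and N*q^2; the statistic sums
    (obs - exp)^2 / exp over the three genotype classes with no continuity
    correction, and the p-value is the upper tail of chi-square with 1 df
    (3 classes - 1 - 1 estimated frequency).  Monomorphic samples (p = 0 or 1)
    report chi2 = 0 with an undefined p-value.
    """
    stats = allele_stats(counts)
    n = counts.N
    p = stats.frequency
    q = 1.0 - p
    exp_rr, exp_rs, exp_ss = n * p * p, 2 * n * p * q, n * q * q
    if p == 0.0 or p == 1.0:
        return HweResult(
            chi2=0.0, p_value=None, df=1,
            expected_RR=exp_rr, expected_RS=exp_rs, expected_SS=exp_ss,
            monomorphic=True,
        )
    chi2 = (
        (counts.n_RR - exp_rr) ** 2 / exp_rr
        + (counts.n_RS - exp_rs) ** 2 / exp_rs
        + (counts.n_SS - exp_ss) ** 2 / exp_ss
    )
    return HweResult(
        chi2=chi2, p_value=float(chi2_dist.sf(chi2, 1)), df=1,
        expected_RR=exp_rr, expected_RS=exp_rs, expected_SS=exp_ss,
        monomorphic=False,
    )


PER_LOCATION_COLUMNS = (
    "location", "N", "n_RR", "n_RS", "n_SS", "kdr_count", "sus_count",
    "allele_frequency", "percent", "chi2", "p_value", "monomorphic", "deviates_hwe",
)


def summarize(
    table: Sequence,
    alpha: float = 0.05,
    denominator_alleles: Optional[int] = None,
    bonferroni: bool = False,
) -> PopulationSummary:
    """Per-location statistics plus survey-level aggregates.

    ``denominator_alleles=None`` (default) computes the percentage column on
    the standard 2N denominator; an integer reproduces the fixed-denominator
    published convention.  ``bonferroni`` divides alpha by the number of
    non-monomorphic locations before counting HWE deviations (off by default:
    the packaged survey applies no multiple-testing correction).
    """
    table = list(table)
    if not table:
        raise ValueError("need at least one location")
    names = [c.location for c in table]
    if len(names) != len(set(names)):
        warnings.warn("duplicate location names in genotype-count table", stacklevel=2)

    non_mono = sum(1 for c in table if 0 < allele_stats(c).frequency < 1)
    eff_alpha = alpha / max(non_mono, 1) if bonferroni else alpha

    rows = []
    for counts in table:
        stats = allele_stats(counts)
        hwe = hwe_test(counts)
        if denominator_alleles is None:
            percent = round_half_up(100.0 * stats.frequency, 1)
        else:
            percent = paper_percent(counts, denominator_alleles)
        deviates = (not hwe.monomorphic) and hwe.p_value < eff_alpha
        rows.append({
            "location": counts.location,
            "N": counts.N,
            "n_RR": counts.n_RR,
            "n_RS": counts.n_RS,
            "n_SS": counts.n_SS,
            "kdr_count": stats.kdr_count,
            "sus_count": stats.sus_count,
            "allele_frequency": stats.frequency,
            "percent": percent,
            "chi2": hwe.chi2,
            "p_value": hwe.p_value,
            "monomorphic": hwe.monomorphic,
            "deviates_hwe": deviates,
        })
    frame = pd.DataFrame(rows, columns=list(PER_LOCATION_COLUMNS))

    total = GenotypeCounts(
        location="TOTAL",
        n_RR=int(frame["n_RR"].sum()),
        n_RS=int(frame["n_RS"].sum()),
        n_SS=int(frame["n_SS"].sum()),
    )
    n_loc = len(table)
    n_with_kdr = int((frame["kdr_count"] >= 1).sum())
    n_with_rr = int((frame["n_RR"] >= 1).sum())
    aggregates = SurveyAggregates(
        total=total,
        pct_RR=100.0 * total.n_RR / total.N,
        pct_RS=100.0 * total.n_RS / total.N,
        n_locations=n_loc,
        n_locations_with_kdr=n_with_kdr,
        n_locations_with_RR=n_with_rr,
        pct_locations_with_RR=round_half_up(100.0 * n_with_rr / n_loc, 1),
        n_locations_deviating_hwe=int(frame["deviates_hwe"].sum()),
        alpha=alpha,
    )
    return PopulationSummary(per_location=frame, aggregates=aggregates)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ("location", "n_RR", "n_RS", "n_SS")


def read_genotype_counts(path: Union[str, Path]) -> list:
    """Read per-location genotype counts from CSV (columns location,n_RR,n_RS,n_SS)."""
    frame = pd.read_csv(path, comment="#")
    if frame.empty:
        raise ValueError(f"genotype-count CSV is empty: {path}")
    missing = [c for c in COUNTS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"genotype-count CSV: missing column(s) {missing}")
    return [
        GenotypeCounts(
            location=str(row["location"]),
            n_RR=int(row["n_RR"]),
            n_RS=int(row["n_RS"]),
            n_SS=int(row["n_SS"]),
        )
        for _, row in frame.iterrows()
    ]


def write_summary(
    summary: PopulationSummary,
    per_location_csv: Union[str, Path],
    aggregate_csv: Optional[Union[str, Path]] = None,
) -> None:
    """Write the per-location table and a one-row aggregate CSV."""
    summary.per_location.to_csv(per_location_csv, index=False)
    if aggregate_csv is not None:
        agg = summary.aggregates
        pd.DataFrame([{
            "N_total": agg.total.N,
            "n_RR": agg.total.n_RR,
            "n_RS": agg.total.n_RS,
            "n_SS": agg.total.n_SS,
            "pct_RR": agg.pct_RR,
            "pct_RS": agg.pct_RS,
            "n_locations": agg.n_locations,
            "n_locations_with_kdr": agg.n_locations_with_kdr,
            "n_locations_with_RR": agg.n_locations_with_RR,
            "pct_locations_with_RR": agg.pct_locations_with_RR,
            "n_locations_deviating_hwe": agg.n_locations_deviating_hwe,
            "alpha": agg.alpha,
        }]).to_csv(aggregate_csv, index=False)
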