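"""Chi-square goodness-of-fit tests of Mendelian segregation.

Expected counts are total * ratio_i / sum(ratio); the statistic is the
plain Pearson chi-square with no continuity correction (back-computation of
published watermelon translocation F2 tables confirms they were computed
without correction: 112:125 against 1:1 gives 0.713 only uncorrected).
A result *conforms* to the tested ratio when the statistic does not exceed
the critical value at the chosen significance level (boundary inclusive).

The two F2 count tables from the source study (pollen-sterility segregation
and codominant-marker genotype classes) ship as packaged TSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass
class ChiSquareResult:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float
    alpha: float
    conforms: bool


def chisq_gof(
    observed: Sequence[int],
    ratio: Sequence[float],
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Pearson chi-square goodness of fit against a segregation ratio.

    ``ratio`` is a vector of positive weights (1:2:1 may be given as
    [1, 2, 1] or any rescaling).  No continuity correction is applied.
    """
    observed = tuple(int(x) for x in observed)
    ratio = tuple(float(r) for r in ratio)
    if len(observed) < 2:
        raise StatsError("need at least 2 classes")
    if len(observed) != len(ratio):
        raise StatsError("observed and ratio must have the same length")
    if any(r <= 0 for r in ratio):
        raise StatsError("ratio weights must be positive")
    total = sum(observed)
    if total <= 0:
        raise StatsError("total count must be positive")
    weight = sum(ratio)
    expected = tuple(total * r / weight for r in ratio)
    if any(e <= 0 for e in expected):
        raise StatsError("zero expected count")
    chi2, p = stats.chisquare(observed, f_exp=expected)
    df = len(observed) - 1
    critical = stats.chi2.ppf(1.0 - alpha, df)
    return ChiSquareResult(
        observed=observed,
        ratio=ratio,
        expected=expected,
        chi2=float(chi2),
        df=df,
        p_value=float(p),
        alpha=alpha,
        conforms=bool(chi2 <= critical),
    )


def classify_segregation(result: ChiSquareResult) -> str:
    """"mendelian" when the tested ratio is not rejected, else "distorted"."""
    return "mendelian" if result.conforms else "distorted"


def format_percent(x: float, digits: int = 1) -> str:
    """Half-up percentage formatting matching the published tables."""
    q = Decimal(10) ** -digits
    return str(Decimal(str(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Contrast:
    """One segregation test: class labels found in ``column`` of a
    population table, tested against ``ratio``."""

    name: str
    column: str
    classes: tuple[str, ...]
    ratio: tuple[float, ...]


def segregation_report(
    population: pd.DataFrame,
    contrasts: Sequence[Contrast],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One chi-square row per contrast from a per-individual table.

    Percentages are printed to one decimal (half-up) and the statistic to
    three decimals, mirroring the published table layout.
    """
    rows = []
    for c in contrasts:
        if c.column not in population.columns:
            raise StatsError(f"population table has no column {c.column!r}")
        values = population[c.column]
        unknown = set(values) - set(c.classes)
        if unknown:
            raise StatsError(f"unknown class labels in {c.column!r}: {sorted(unknown)}")
        counts = [int((values == cls).sum()) for cls in c.classes]
        res = chisq_gof(counts, c.ratio, alpha)
        total = sum(counts)
        row = {"contrast": c.name, "n": total}
        for cls, cnt in zip(c.classes, counts):
            row[cls] = cnt
            row[f"{cls}_pct"] = format_percent(cnt / total)
        row["ratio"] = ":".join(f"{r:g}" for r in c.ratio)
        row["chi2"] = round(res.chi2, 3)
        row["df"] = res.df
        row["p_value"] = res.p_value
        row["segregation"] = classify_segregation(res)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged F2 count fixtures from the source study
# ---------------------------------------------------------------------------


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("translokit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pollen_f2_counts() -> pd.DataFrame:
    """Pollen fertility segregation in three F2 populations (normal vs
    sterile plant counts and the tested ratio)."""
    return _load_table("pollen_f2_counts.tsv")


def load_marker_f2_counts() -> pd.DataFrame:
    """Codominant-marker genotype counts (homozygous WT / heterozygous /
    homozygous translocated) in three F2 populations."""
    return _load_table("marker_f2_counts.tsv")


def _parse_ratio(text: str) -> tuple[float, ...]:
    return tuple(float(x) for x in text.split(":"))


def pollen_f2_report(alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square rows recomputed from the packaged pollen-count fixture."""
    df = load_pollen_f2_counts()
    rows = []
    for _, r in df.iterrows():
        res = chisq_gof([r["normal_pollen"], r["sterile_pollen"]],
                        _parse_ratio(r["ratio"]), alpha)
        total = r["normal_pollen"] + r["sterile_pollen"]
        rows.append({
            "f2_line": r["f2_line"],
            "n": total,
            "normal_pollen": r["normal_pollen"],
            "normal_pct": format_percent(r["normal_pollen"] / total),
            "sterile_pollen": r["sterile_pollen"],
            "sterile_pct": format_percent(r["sterile_pollen"] / total),
            "ratio": r["ratio"],
            "chi2": round(res.chi2, 3),
            "segregation": classify_segregation(res),
        })
    return pd.DataFrame(rows)


def marker_f2_report(alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square rows recomputed from the packaged marker-count fixture."""
    df = load_marker_f2_counts()
    rows = []
    for _, r in df.iterrows():
        counts = [r["homozygous_wt"], r["heterozygous_tl"], r["homozygous_tl"]]
        res = chisq_gof(counts, _parse_ratio(r["ratio"]), alpha)
        total = sum(counts)
        rows.append({
            "f2_line": r["f2_line"],
            "marker": r["marker"],
            "n": total,
            "homozygous_wt": counts[0],
            "heterozygous_tl": counts[1],
            "homozygous_tl": counts[2],
            "ratio": r["ratio"],
            "chi2": round(res.chi2, 3),
            "segregation": classify_segregation(res),
        })
    return pd.DataFrame(rows)
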