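"""Region aggregation and group-comparison statistics.

Contrast maps are averaged over labeled regions into a tidy per-subject
table, then compared across study arms with the scheme the emulated study
reports: an omnibus one-way ANOVA across all arms, a pooled two-tailed t
test for baseline vs the 6-week timepoint, a Welch two-tailed t test for
baseline vs the 12-week vehicle arm (unequal group sizes), and a post-hoc
two-tailed t test for treated vs vehicle at 12 weeks.  Arms are treated as
independent groups (matching the reported tests) even though the early
timepoints re-scan the same animals; a paired mode exists but is off by
default.  No multiplicity correction is applied across regions or pools by
default, again matching the reported analysis; Holm correction is
available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contrast import ContrastMap

__all__ = ["StatsError", "TestReport", "ComparisonScheme", "aggregate_regions",
           "omnibus_anova", "pairwise_ttest", "paired_ttest", "tier",
           "comparison_suite", "summary_table"]

log = logging.getLogger(__name__)

#: half-open significance bins, most significant first
TIER_BINS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "#"),
)


class StatsError(ValueError):
    """Raised for structural problems in the statistics layer."""


@dataclass
class TestReport:
    """One hypothesis test: identity, statistic, p, significance tier."""

    comparison: str
    variant: str            # pooled | welch | anova | paired | degenerate
    statistic: float
    df: float | tuple[float, float]
    p: float
    tier: str
    region: str = ""
    pool: str = ""
    note: str = ""

    def to_dict(self) -> dict:
        df = self.df if not isinstance(self.df, tuple) else f"{self.df[0]:g},{self.df[1]:g}"
        return {"region": self.region, "pool": self.pool,
                "comparison": self.comparison, "variant": self.variant,
                "statistic": self.statistic, "df": df, "p": self.p,
                "tier": self.tier, "note": self.note}


def tier(p: float) -> str:
    """Map a p-value to the study's significance label.

    Half-open bins: [0, 1e-4) -> "****", [1e-4, 1e-3) -> "***",
    [1e-3, 0.01) -> "**", [0.01, 0.05) -> "*", [0.05, 0.1) -> "#",
    [0.1, 1] -> "ns".
    """
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValueError(f"p must be in [0, 1], got {p}")
    for cut, label in TIER_BINS:
        if p < cut:
            return label
    return "ns"


def aggregate_regions(cmap: ContrastMap, labels: np.ndarray,
                      region_ids: dict[int, str], subject: str, arm: str,
                      ) -> list[dict]:
    """Per-region mean of unmasked voxels -> tidy table rows.

    Regions with no unmasked voxel are omitted (missing data, not zero).
    Label values not in ``region_ids`` (other than background 0) raise.
    """
    labels = np.asarray(labels)
    if labels.shape != cmap.values.shape:
        raise StatsError(f"label map shape {labels.shape} != map shape "
                         f"{cmap.values.shape}")
    present = set(np.unique(labels)) - {0}
    unknown = present - set(region_ids)
    if unknown:
        raise StatsError(f"label ids {sorted(unknown)} missing from region registry "
                         f"{sorted(region_ids)}")
    rows = []
    for rid, name in region_ids.items():
        sel = (labels == rid) & cmap.mask
        if not sel.any():
            log.warning("region %s: no unmasked voxels for subject %s", name, subject)
            continue
        rows.append({"subject": subject, "arm": arm, "region": name,
                     "pool": cmap.pool, "contrast": float(cmap.values[sel].mean())})
    return rows


def _degenerate(comparison: str, variant: str, note: str, region="", pool="") -> TestReport:
    return TestReport(comparison=comparison, variant="degenerate", statistic=np.nan,
                      df=np.nan, p=np.nan, tier="degenerate", region=region,
                      pool=pool, note=note)


def omnibus_anova(groups: dict[str, np.ndarray], region: str = "",
                  pool: str = "") -> TestReport:
    """Ordinary one-way fixed-effects ANOVA across arms.

    Arms with fewer than 2 values are excluded with a warning; all-constant
    data (zero within-group variance everywhere) yields an explicit
    degenerate report rather than NaN propagation.
    """
    usable = {a: np.asarray(v, dtype=float) for a, v in groups.items()
              if np.asarray(v).size >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        warnings.warn(f"ANOVA: arms {dropped} excluded (< 2 subjects)")
    if len(usable) < 2:
        raise StatsError("ANOVA needs >= 2 arms with >= 2 subjects each")
    vals = list(usable.values())
    label = "anova:" + "|".join(usable)
    if all(np.ptp(v) == 0 for v in vals):
        if np.ptp(np.concatenate(vals)) == 0:
            return _degenerate(label, "anova", "zero within- and between-group variance",
                               region, pool)
        return _degenerate(label, "anova", "zero within-group variance", region, pool)
    f, p = sps.f_oneway(*vals)
    k = len(vals)
    n = sum(v.size for v in vals)
    rep = TestReport(comparison=label, variant="anova", statistic=float(f),
                     df=(float(k - 1), float(n - k)), p=float(p), tier=tier(float(p)),
                     region=region, pool=pool)
    return rep


def pairwise_ttest(a: np.ndarray, b: np.ndarray, variant: str = "pooled",
                   comparison: str = "", region: str = "", pool: str = "") -> TestReport:
    """Two-tailed two-sample t test, pooled-variance or Welch.

    Welch uses the Welch–Satterthwaite degrees of freedom.  Zero variance
    in both groups with equal means is reported as degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError(f"each group needs n >= 2 (got {a.size}, {b.size})")
    if variant not in ("pooled", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    label = comparison or f"ttest[{variant}]"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return _degenerate(label, variant, "zero variance, equal means",
                               region, pool)
        return TestReport(comparison=label, variant=variant, statistic=np.inf,
                          df=float(a.size + b.size - 2), p=0.0, tier=tier(0.0),
                          region=region, pool=pool, note="zero variance, unequal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestReport(comparison=label, variant=variant, statistic=float(res.statistic),
                      df=float(res.df), p=float(res.pvalue), tier=tier(float(res.pvalue)),
                      region=region, pool=pool)


def paired_ttest(a: np.ndarray, b: np.ndarray, comparison: str = "",
                 region: str = "", pool: str = "") -> TestReport:
    """Two-tailed paired t test (optional mode; the default scheme is unpaired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise StatsError("paired test needs equal-length groups with n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return _degenerate(comparison or "paired", "paired",
                               "identical pairs", region, pool)
    res = sps.ttest_rel(a, b)
    return TestReport(comparison=comparison or "paired", variant="paired",
                      statistic=float(res.statistic), df=float(a.size - 1),
                      p=float(res.pvalue), tier=tier(float(res.pvalue)),
                      region=region, pool=pool)


@dataclass
class ComparisonScheme:
    """Which pairwise contrasts to run, and with which variance model.

    The default mirrors the emulated study: baseline↔wk6 pooled,
    baseline↔wk12_vehicle Welch, wk12_art↔wk12_vehicle pooled (the report
    wording leaves the post-hoc variant ambiguous; pooled is the default
    and configurable), plus the omnibus ANOVA over all arms.
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=lambda: [
        ("baseline", "wk6", "pooled"),
        ("baseline", "wk12_vehicle", "welch"),
        ("wk12_art", "wk12_vehicle", "pooled"),
    ])
    anova: bool = True
    paired: bool = False
    holm: bool = False


def _holm(reports: list[TestReport]) -> None:
    idx = [i for i, r in enumerate(reports)
           if r.variant != "degenerate" and np.isfinite(r.p)]
    m = len(idx)
    order = sorted(idx, key=lambda i: reports[i].p)
    prev = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * reports[i].p)
        adj = max(adj, prev)
        prev = adj
        reports[i].p = adj
        reports[i].tier = tier(adj)
        reports[i].note = (reports[i].note + " holm-adjusted").strip()


def comparison_suite(table: pd.DataFrame, scheme: ComparisonScheme | None = None,
                     ) -> tuple[list[TestReport], pd.DataFrame]:
    """Run the full comparison scheme per (region, pool).

    ``table`` is tidy with columns subject/arm/region/pool/contrast.
    Returns the test reports and a mean ± SEM summary per arm/region/pool.
    Comparisons whose arms are missing (or under-sized) are skipped with a
    warning, never fabricated.
    """
    if scheme is None:
        scheme = ComparisonScheme()
    required = {"subject", "arm", "region", "pool", "contrast"}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(table["contrast"])):
        raise StatsError("table contains non-finite contrast values")

    reports: list[TestReport] = []
    for (region, pool), sub in table.groupby(["region", "pool"], sort=True):
        groups = {arm: g["contrast"].to_numpy()
                  for arm, g in sub.groupby("arm", sort=False)}
        if scheme.anova:
            try:
                reports.append(omnibus_anova(groups, region=region, pool=pool))
            except StatsError as exc:
                warnings.warn(f"{region}/{pool}: ANOVA skipped ({exc})")
        for arm_a, arm_b, variant in scheme.pairs:
            label = f"{arm_a} vs {arm_b}"
            if arm_a not in groups or arm_b not in groups:
                warnings.warn(f"{region}/{pool}: '{label}' skipped (missing arm)")
                continue
            try:
                if scheme.paired:
                    reports.append(paired_ttest(groups[arm_a], groups[arm_b],
                                                comparison=label, region=region,
                                                pool=pool))
                else:
                    reports.append(pairwise_ttest(groups[arm_a], groups[arm_b],
                                                  variant=variant, comparison=label,
                                                  region=region, pool=pool))
            except StatsError as exc:
                warnings.warn(f"{region}/{pool}: '{label}' skipped ({exc})")
    if scheme.holm:
        _holm(reports)
    return reports, summary_table(table)


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM (ddof=1) per (arm, region, pool)."""
    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan

    out = (table.groupby(["region", "pool", "arm"], sort=True)["contrast"]
           .agg(n="size", mean="mean", sem=sem).reset_index())
    return out


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
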