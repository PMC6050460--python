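"""Cross-method cohort statistics: percent SUVR changes and PET-histology
Pearson correlations.

The report answers two questions for each correction method: how much does
it move the target-region SUVR relative to no correction (per-subject percent
change, summarised two ways), and does it change the strength of the
correlation between SUVR and the histological percent-area measures of
amyloid load.  Significance uses a fixed two-sided alpha (default 0.01)
without multiple-testing correction; the report metadata flags this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METHOD_ORDER = ("none", "meltzer", "mmg", "rbv")
HISTOLOGY_MEASURES = ("h6cnpib_pct", "h4g8_pct")
DEFAULT_ALPHA = 0.01


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    r is computed from the definition (centred cross-moments); the p-value
    comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom, with
    p = 0 at |r| = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("constant input has undefined correlation")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r < 1e-15:
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    histology_measure: str
    n: int
    r: float
    p: float
    significant: bool

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0) or not (0.0 <= self.p <= 1.0):
            raise ValueError("r or p out of range")


@dataclass
class PercentChangeSummary:
    """Per-subject percent SUVR changes of one method versus no correction.

    ``mean_pct`` averages the per-subject percent changes;
    ``pct_of_means`` is the percent change of the mean SUVRs — the other
    reading of "on average increased by X %".  Both are reported.
    """

    method: str
    subject_ids: list[str]
    per_subject_pct: np.ndarray
    mean_pct: float
    pct_of_means: float
    n_decreased: int


def percent_change(
    suvr_none, suvr_pvc, method: str = "", subject_ids=None
) -> PercentChangeSummary:
    """Percent change of corrected vs uncorrected SUVR, per subject.

    pct_i = 100 * (pvc_i - none_i) / none_i; also reports the count of
    subjects whose SUVR decreased under correction.
    """
    a = np.asarray(suvr_none, dtype=np.float64)
    b = np.asarray(suvr_pvc, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("mismatched subject vectors")
    if np.any(a <= 0):
        raise ValueError("uncorrected SUVR must be positive")
    pct = 100.0 * (b - a) / a
    if subject_ids is None:
        subject_ids = [str(i) for i in range(a.size)]
    return PercentChangeSummary(
        method=method,
        subject_ids=list(subject_ids),
        per_subject_pct=pct,
        mean_pct=float(pct.mean()),
        pct_of_means=float(100.0 * (b.mean() - a.mean()) / a.mean()),
        n_decreased=int((pct < 0).sum()),
    )


def percent_change_table(suvr_table: pd.DataFrame) -> pd.DataFrame:
    """Percent-change summaries for every corrected method in a SUVR table.

    ``suvr_table`` needs columns subject_id, method, suvr and must contain
    the "none" method.
    """
    wide = suvr_table.pivot(index="subject_id", columns="method", values="suvr")
    if "none" in wide.columns and wide["none"].isna().any():
        raise ValueError("missing uncorrected SUVR for some subjects")
    if "none" not in wide.columns:
        raise ValueError("SUVR table lacks the uncorrected ('none') method")
    rows = []
    for method in [m for m in METHOD_ORDER if m != "none" and m in wide.columns]:
        summary = percent_change(
            wide["none"].to_numpy(),
            wide[method].to_numpy(),
            method=method,
            subject_ids=list(wide.index),
        )
        rows.append(
            {
                "method": method,
                "mean_pct": summary.mean_pct,
                "pct_of_means": summary.pct_of_means,
                "n_decreased": summary.n_decreased,
                "min_pct": float(summary.per_subject_pct.min()),
                "max_pct": float(summary.per_subject_pct.max()),
            }
        )
    return pd.DataFrame(rows)


def correlation_report(
    suvr_table: pd.DataFrame,
    histology_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pearson correlations of every method's SUVR against each histology
    measure, plus the histology-histology pair.

    Tables are joined on subject_id; any unmatched subject raises rather
    than being silently dropped.  Within each histology measure methods are
    ranked by r (descending); the histology pair row comes last with
    method = "histology".
    """
    needed = {"subject_id", "method", "suvr"}
    if not needed <= set(suvr_table.columns):
        raise ValueError(f"SUVR table needs columns {sorted(needed)}")
    hist_ids = set(histology_table["subject_id"])
    suvr_ids = set(suvr_table["subject_id"])
    if hist_ids != suvr_ids:
        raise ValueError(
            "subject ids differ between SUVR and histology tables: "
            f"{sorted(hist_ids ^ suvr_ids)}"
        )
    hist = histology_table.set_index("subject_id")
    rows: list[CorrelationResult] = []
    methods = [m for m in METHOD_ORDER if m in set(suvr_table["method"])]
    for measure in HISTOLOGY_MEASURES:
        for method in methods:
            sub = suvr_table[suvr_table["method"] == method].set_index("subject_id")
            joined = sub.join(hist, how="inner")
            r, p = pearson(joined["suvr"], joined[measure])
            rows.append(
                CorrelationResult(
                    method=method,
                    histology_measure=measure,
                    n=len(joined),
                    r=r,
                    p=p,
                    significant=p < alpha,
                )
            )
    r, p = pearson(hist["h6cnpib_pct"], hist["h4g8_pct"])
    pair = CorrelationResult(
        method="histology",
        histology_measure="h6cnpib_pct~h4g8_pct",
        n=len(hist),
        r=r,
        p=p,
        significant=p < alpha,
    )
    df = pd.DataFrame([vars(row) for row in rows])
    df = (
        df.sort_values(["histology_measure", "r"], ascending=[True, False])
        .reset_index(drop=True)
    )
    df = pd.concat([df, pd.DataFrame([vars(pair)])], ignore_index=True)
    df.attrs["alpha"] = alpha
    df.attrs["multiple_testing_correction"] = "none"
    return df


def summarize_report(
    pct_table: pd.DataFrame, corr_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> str:
    """Human-readable text summary of the two report tables."""
    lines = ["Percent SUVR change vs no correction (target VOI, GM only):"]
    for _, row in pct_table.iterrows():
        lines.append(
            f"  {row['method']:>8s}: mean of per-subject changes "
            f"{row['mean_pct']:+7.1f} % (change of means {row['pct_of_means']:+7.1f} %), "
            f"{int(row['n_decreased'])} subject(s) decreased"
        )
    lines.append("")
    lines.append(
        f"Pearson correlations (two-sided, alpha={alpha:g}, "
        "no multiple-testing correction):"
    )
    for _, row in corr_table.iterrows():
        flag = "significant" if row["significant"] else "not significant"
        lines.append(
            f"  {row['method']:>9s} vs {row['histology_measure']:<22s} "
            f"r={row['r']:+.3f}  p={row['p']:.2e}  n={int(row['n'])}  [{flag}]"
        )
    return "\n".join(lines)
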