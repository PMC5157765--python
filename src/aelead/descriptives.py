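"""Cross-source descriptive comparisons.

Reproduces the structure of the summary tables comparing the two report
streams: demographics, specific-AE and seriousness proportions,
satisfaction ratings (social media only), the top-K AE frequency tables,
how concentrated each stream's reporting is on its top-K categories, and
the overlap of top categories across streams.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# elementary two-sample comparisons


def compare_means(x, y, method: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test for a difference in means.

    ``student`` pools the variance (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite degrees of freedom. Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    if method == "student":
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        if sp2 == 0:
            raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(x, y, equal_var=(method == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_proportions(n1: int, N1: int, n2: int, N2: int) -> tuple[float, float, float]:
    """Pooled two-proportion z-test (two-sided).

    Returns ``(z, chi2, p)`` where chi2 = z**2 is the equivalent 1-df
    chi-square statistic. A degenerate pooled proportion (0 or 1) yields
    p = 1 with a warning.
    """
    for n, N in ((n1, N1), (n2, N2)):
        if N < 1 or not 0 <= n <= N:
            raise ValueError("need 0 <= n <= N and N >= 1 in both groups")
    p_pool = (n1 + n2) / (N1 + N2)
    if p_pool in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; test uninformative")
        return 0.0, 0.0, 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / N1 + 1 / N2))
    z = (n1 / N1 - n2 / N2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(z * z), float(p)


# --------------------------------------------------------------------------
# summary table


def _pct(n: float, d: float) -> float:
    return 100.0 * n / d if d else 0.0


@dataclass
class SummaryTable:
    """Per-stream summary statistics plus cross-stream tests."""

    specific_ae: str
    per_stream: pd.DataFrame  # one row per stream
    comparisons: pd.DataFrame  # one row per tested quantity

    def to_frame(self) -> pd.DataFrame:
        return self.per_stream


def _stream_summary(records: pd.DataFrame, specific_ae: str, stream: str) -> dict:
    n = len(records)
    out: dict = {"stream": stream, "N": n}
    age = records["age"] if "age" in records else pd.Series(dtype=float)
    age = pd.to_numeric(age, errors="coerce").dropna()
    gender = records["gender"] if "gender" in records else pd.Series(dtype=str)
    known_gender = gender[gender.isin(["F", "M"])] if len(gender) else gender
    out["n_female"] = int((known_gender == "F").sum())
    out["n_gender_known"] = int(len(known_gender))
    out["pct_female"] = _pct(out["n_female"], out["n_gender_known"])
    out["age_mean"] = float(age.mean()) if len(age) else np.nan
    out["age_sd"] = float(age.std(ddof=1)) if len(age) > 1 else np.nan
    out["n_age_known"] = int(len(age))

    flag_col = f"has_{specific_ae}"
    flags = records[flag_col].astype(bool) if flag_col in records else pd.Series(False, index=records.index)
    serious = (
        records["serious_derived"].astype(bool)
        if "serious_derived" in records
        else pd.Series(False, index=records.index)
    )
    n_spec = int(flags.sum())
    n_ser_spec = int((flags & serious).sum())
    out["n_specific"] = n_spec
    out["pct_specific"] = _pct(n_spec, n)
    out["n_serious_specific"] = n_ser_spec
    out["pct_serious_specific"] = _pct(n_ser_spec, n_spec)

    if stream == "social_media" and "rating" in records:
        rating = pd.to_numeric(records["rating"], errors="coerce")
        for label, mask in (
            ("overall", pd.Series(True, index=records.index)),
            ("specific", flags),
            ("serious_specific", flags & serious),
        ):
            vals = rating[mask].dropna()
            out[f"rating_mean_{label}"] = float(vals.mean()) if len(vals) else np.nan
            out[f"rating_sd_{label}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return out


def summarize(sm, reg, specific_ae: str) -> SummaryTable:
    """Build the cross-source summary table for one named specific AE.

    ``sm`` and ``reg`` are classified CleanDatasets (or bare record
    frames); either may be None. Missing age/gender values are excluded
    from the corresponding denominators. Empty inputs yield a zero table
    without division errors.
    """
    rows = []
    frames = {}
    for ds, stream in ((sm, "social_media"), (reg, "regulatory")):
        if ds is None:
            continue
        records = getattr(ds, "records", ds)
        frames[stream] = records
        rows.append(_stream_summary(records, specific_ae, stream))
    per_stream = pd.DataFrame(rows)

    comparisons = []
    if len(rows) == 2:
        a, b = rows
        fa, fb = frames["social_media"], frames["regulatory"]
        age_a = pd.to_numeric(fa.get("age", pd.Series(dtype=float)), errors="coerce").dropna()
        age_b = pd.to_numeric(fb.get("age", pd.Series(dtype=float)), errors="coerce").dropna()
        if len(age_a) >= 2 and len(age_b) >= 2:
            t, df, p = compare_means(age_a, age_b, "student")
            comparisons.append({"quantity": "age_mean", "statistic": t, "p_value": p})
        if a["n_gender_known"] and b["n_gender_known"]:
            z, _, p = compare_proportions(
                a["n_female"], a["n_gender_known"], b["n_female"], b["n_gender_known"]
            )
            comparisons.append({"quantity": "pct_female", "statistic": z, "p_value": p})
        if a["N"] and b["N"]:
            z, _, p = compare_proportions(a["n_specific"], a["N"], b["n_specific"], b["N"])
            comparisons.append({"quantity": "pct_specific", "statistic": z, "p_value": p})
        if a["n_specific"] and b["n_specific"]:
            z, _, p = compare_proportions(
                a["n_serious_specific"], a["n_specific"],
                b["n_serious_specific"], b["n_specific"],
            )
            comparisons.append({"quantity": "pct_serious_specific", "statistic": z, "p_value": p})
    return SummaryTable(
        specific_ae=specific_ae,
        per_stream=per_stream,
        comparisons=pd.DataFrame(comparisons, columns=["quantity", "statistic", "p_value"]),
    )


# --------------------------------------------------------------------------
# top-K tables, concentration, overlap


@dataclass
class TopKTable:
    """Ranked AE categories with per-stream percentages and concentration."""

    stream: str
    k: int
    table: pd.DataFrame  # rank, category, n, pct
    concentration: dict[int, float]  # k -> fraction of reports in top-k
    note: str = ""

    @property
    def categories(self) -> list[str]:
        return self.table["category"].tolist()


def top_k_table(dataset, k: int = 20) -> TopKTable:
    """Rank AE categories by the share of reports mentioning them.

    Percentages use the stream's N as denominator; because records are
    multi-label the column may sum to more than 100%. Concentration_k is
    the fraction of unique reports mentioning at least one top-k category
    (each report counted once however many top-k categories it mentions).
    Ties in the ranking break alphabetically.
    """
    records = getattr(dataset, "records", dataset)
    stream = getattr(dataset, "stream", "unknown")
    n = len(records)
    cat_sets = records["ae_categories"] if n else pd.Series(dtype=object)
    counts: dict[str, int] = {}
    for cats in cat_sets:
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    note = ""
    if k > len(ranked):
        note = f"k={k} exceeds {len(ranked)} observed categories; using all"
        k_eff = len(ranked)
    else:
        k_eff = k
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "category": [c for c, _ in ranked],
            "n": [v for _, v in ranked],
            "pct": [_pct(v, n) for _, v in ranked],
        }
    )
    concentration = {}
    for kk in sorted({10, 20, k_eff}):
        top = {c for c, _ in ranked[:kk]}
        hit = sum(1 for cats in cat_sets if not top.isdisjoint(cats))
        concentration[kk] = hit / n if n else 0.0
    return TopKTable(
        stream=stream,
        k=k_eff,
        table=table.iloc[:k_eff].reset_index(drop=True),
        concentration=concentration,
        note=note,
    )


def category_overlap(sm_table: TopKTable, reg_table: TopKTable, mapping: dict[str, str]) -> int:
    """Count top categories shared across streams under a concept map.

    ``mapping`` translates social-media category labels to regulatory
    category labels (hand-matched concepts); unmapped labels never match.
    """
    sm_mapped = {mapping.get(c) for c in sm_table.categories} - {None}
    return len(sm_mapped & set(reg_table.categories))
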