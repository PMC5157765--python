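"""Parsing, exclusion rules, and AE classification for both report streams.

Social-media reviews are free-text; regulatory reports carry coded PTs.
Sample-selection rules mirror standard spontaneous-report practice:
reviews with no usable side-effect information, second-hand (hearsay)
reviews, and obvious duplicates are excluded; regulatory reports are kept
only when the study drug is the primary suspect and the report came from a
consumer or health professional (trial/literature reports optionally
retained as a sensitivity analysis).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import TermHierarchy

logger = logging.getLogger(__name__)

REVIEW_COLUMNS = ("record_id", "post_date", "age", "gender", "drug", "rating", "side_effects", "comments")
REPORT_COLUMNS = ("record_id", "fda_date", "age", "gender", "drug", "drug_role", "report_source", "pt_terms", "serious")

DRUG_ROLES = {"primary_suspect", "secondary_suspect", "concomitant", "interacting"}
REPORT_SOURCES = {"consumer", "health_professional", "clinical_trial", "literature"}


class SchemaError(ValueError):
    """A mandatory input column is missing."""


@dataclass
class CleanDataset:
    """Records surviving the exclusion rules, plus the exclusion log.

    ``records`` carries the canonical parsed columns and, after
    :func:`classify`, the derived columns ``ae_categories`` (set of
    labels), ``has_<name>`` per specific-AE filter, and
    ``serious_derived``. ``exclusions`` has columns (record_id, reason).
    """

    records: pd.DataFrame
    exclusions: pd.DataFrame
    stream: str

    def __post_init__(self):
        if len(self.records) and len(self.exclusions):
            both = set(self.records["record_id"]) & set(self.exclusions["record_id"])
            if both:
                raise ValueError(f"records present in both survivors and exclusion log: {sorted(both)[:5]}")

    @property
    def n(self) -> int:
        return len(self.records)


def _empty_exclusions() -> pd.DataFrame:
    return pd.DataFrame({"record_id": pd.Series(dtype=str), "reason": pd.Series(dtype=str)})


def _log_exclusions(frames, ids, reason) -> None:
    if len(ids):
        frames.append(pd.DataFrame({"record_id": list(ids), "reason": reason}))


def parse_reports(path, stream: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one stream's CSV into the canonical record frame.

    Malformed dates and ages become missing values with a logged warning;
    structurally invalid rows (e.g. a rating outside 1..5) go to the
    returned exclusion frame. Missing mandatory columns raise
    :class:`SchemaError` naming the column.
    """
    if stream not in ("social_media", "regulatory"):
        raise ValueError(f"unknown stream {stream!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = REVIEW_COLUMNS if stream == "social_media" else REPORT_COLUMNS
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"{stream} file missing mandatory column {col!r}")

    date_col = "post_date" if stream == "social_media" else "fda_date"
    dates = pd.to_datetime(raw[date_col], format="%Y-%m-%d", errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("%d malformed dates in %s set to missing", n_bad, path)
    ages = pd.to_numeric(raw["age"], errors="coerce")
    n_bad = int(ages.isna().sum() - (raw["age"] == "").sum())
    if n_bad > 0:
        logger.warning("%d malformed ages in %s set to missing", n_bad, path)
    ages = ages.where((ages >= 0) & (ages <= 120))
    gender = raw["gender"].str.upper().where(raw["gender"].str.upper().isin(["F", "M"]), "")

    rec = pd.DataFrame(
        {
            "record_id": raw["record_id"],
            "stream": stream,
            "event_month": dates.dt.to_period("M"),
            "event_day": dates.dt.day,
            "age": ages,
            "gender": gender,
            "drug": raw["drug"],
        }
    )
    exclusions = []
    if stream == "social_media":
        rating = pd.to_numeric(raw["rating"], errors="coerce")
        rec["rating"] = rating
        rec["raw_text"] = (raw["side_effects"].fillna("") + " " + raw["comments"].fillna("")).str.strip()
        bad_rating = rating.isna() | (rating < 1) | (rating > 5) | (rating != rating.round())
        _log_exclusions(exclusions, rec.loc[bad_rating, "record_id"], "invalid rating")
        rec = rec[~bad_rating]
    else:
        rec["coded_terms"] = raw["pt_terms"].map(lambda s: tuple(t for t in s.split(";") if t))
        rec["serious"] = pd.to_numeric(raw["serious"], errors="coerce").fillna(0).astype(bool)
        rec["drug_role"] = raw["drug_role"].where(raw["drug_role"].isin(DRUG_ROLES), "")
        rec["report_source"] = raw["report_source"].where(raw["report_source"].isin(REPORT_SOURCES), "")
    excl = pd.concat(exclusions, ignore_index=True) if exclusions else _empty_exclusions()
    return rec.reset_index(drop=True), excl


def apply_review_exclusions(
    records: pd.DataFrame,
    vocab: TermHierarchy,
    prior_exclusions: pd.DataFrame | None = None,
) -> CleanDataset:
    """Apply the social-media sample-selection rules.

    In order: (i) hearsay (text matches a second-hand-report trigger),
    (ii) insufficient information (text matches no lexicon category and no
    seriousness trigger), (iii) exact duplicates on
    (raw_text, age, gender, month), keeping the earliest. Idempotent:
    running the survivors through again excludes nothing.
    """
    rec = records.copy()
    exclusions = [] if prior_exclusions is None or prior_exclusions.empty else [prior_exclusions.copy()]
    if len(rec):
        no_month = rec["event_month"].isna()
        _log_exclusions(exclusions, rec.loc[no_month, "record_id"], "missing date")
        rec = rec[~no_month]
        text = rec["raw_text"].astype(str)
        hearsay = text.map(vocab.is_hearsay)
        _log_exclusions(exclusions, rec.loc[hearsay, "record_id"], "hearsay")
        rec = rec[~hearsay]
        text = rec["raw_text"].astype(str)
        insufficient = ~(
            text.map(lambda t: bool(vocab.categories_of_text(t)))
            | text.map(vocab.is_serious_text)
        )
        _log_exclusions(exclusions, rec.loc[insufficient, "record_id"], "insufficient")
        rec = rec[~insufficient]
        # earliest = smallest day within the month, ties by file order;
        # a record with unknown age or gender is never an "obvious" duplicate
        order = rec.sort_values(["event_day"], kind="stable")
        comparable = order["age"].notna() & (order["gender"] != "")
        key = ["raw_text", "age", "gender", "event_month"]
        dup = order.duplicated(subset=key, keep="first") & comparable
        dup_ids = order.loc[dup, "record_id"]
        _log_exclusions(exclusions, dup_ids, "duplicate")
        rec = rec[~rec["record_id"].isin(set(dup_ids))]
    excl = pd.concat(exclusions, ignore_index=True) if exclusions else _empty_exclusions()
    return CleanDataset(records=rec.reset_index(drop=True), exclusions=excl, stream="social_media")


def apply_regulatory_filters(
    records: pd.DataFrame,
    include_trial_literature: bool = False,
    prior_exclusions: pd.DataFrame | None = None,
) -> CleanDataset:
    """Keep primary-suspect reports from consumer / health-professional
    sources; ``include_trial_literature=True`` additionally retains
    clinical-trial and literature reports (sensitivity analysis)."""
    rec = records.copy()
    exclusions = [] if prior_exclusions is None or prior_exclusions.empty else [prior_exclusions.copy()]
    if len(rec):
        no_month = rec["event_month"].isna()
        _log_exclusions(exclusions, rec.loc[no_month, "record_id"], "missing date")
        rec = rec[~no_month]
        bad_role = rec["drug_role"] != "primary_suspect"
        _log_exclusions(exclusions, rec.loc[bad_role, "record_id"], "not primary suspect")
        rec = rec[~bad_role]
        allowed = {"consumer", "health_professional"}
        if include_trial_literature:
            allowed |= {"clinical_trial", "literature"}
        bad_src = ~rec["report_source"].isin(allowed)
        _log_exclusions(exclusions, rec.loc[bad_src, "record_id"], "excluded source")
        rec = rec[~bad_src]
    excl = pd.concat(exclusions, ignore_index=True) if exclusions else _empty_exclusions()
    return CleanDataset(records=rec.reset_index(drop=True), exclusions=excl, stream="regulatory")


def classify(dataset: CleanDataset, vocab: TermHierarchy, level: str = "hlt") -> CleanDataset:
    """Attach derived AE columns to a clean dataset.

    Social media: categories from lexicon phrase matches on the lowercased
    text; ``serious_derived`` true iff the text matches an FDA-style
    serious-outcome trigger. Regulatory: categories are the HLTs (or HLGTs
    with ``level='hlgt'``) of the coded PTs; ``serious_derived`` is the
    report's serious flag. One record can contribute to several
    categories. Each ``has_<name>`` flag marks membership in that named
    specific-AE filter.
    """
    rec = dataset.records.copy()
    if dataset.stream == "social_media":
        texts = rec["raw_text"].astype(str) if len(rec) else pd.Series(dtype=str)
        cats = texts.map(vocab.categories_of_text)
        serious = texts.map(vocab.is_serious_text)
        rec["ae_categories"] = cats
        rec["serious_derived"] = serious.astype(bool) if len(rec) else serious
        for name, d in vocab.specific.items():
            rec[f"has_{name}"] = cats.map(d.matches_categories) if len(rec) else pd.Series(dtype=bool)
    else:
        terms = rec["coded_terms"] if len(rec) else pd.Series(dtype=object)
        rec["ae_categories"] = terms.map(lambda pts: vocab.categories_of_pts(pts, level=level))
        rec["serious_derived"] = rec["serious"].astype(bool) if len(rec) else pd.Series(dtype=bool)
        for name in vocab.specific:
            rec[f"has_{name}"] = (
                terms.map(lambda pts: vocab.specific_flag_for_pts(name, pts))
                if len(rec)
                else pd.Series(dtype=bool)
            )
    return CleanDataset(records=rec, exclusions=dataset.exclusions, stream=dataset.stream)


def ingest(
    reviews_csv,
    reports_csv,
    vocab: TermHierarchy,
    include_trial_literature: bool = False,
    level: str = "hlt",
) -> tuple[CleanDataset, CleanDataset]:
    """Parse, filter, and classify both streams in one call."""
    sm_rec, sm_excl = parse_reports(reviews_csv, "social_media")
    reg_rec, reg_excl = parse_reports(reports_csv, "regulatory")
    sm = classify(apply_review_exclusions(sm_rec, vocab, prior_exclusions=sm_excl), vocab, level=level)
    reg = classify(
        apply_regulatory_filters(reg_rec, include_trial_literature, prior_exclusions=reg_excl),
        vocab,
        level=level,
    )
    return sm, reg
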