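"""Synthetic paired adverse-event report streams.

Generates a social-media review stream and a regulatory report stream with
known statistical structure: a configurable lead-lag coupling between the
two monthly count processes, stream-specific demographics (social-media
reporters younger, mostly female for the anorectic-like preset), AE
category mixtures patterned on the observed top-20 frequency tables of the
two streams, and a seriousness gap (regulatory reports far more often
serious). Junk reviews (hearsay, insufficient, duplicates) and
non-analysable regulatory reports (non-primary-suspect roles,
trial/literature sources) are injected as flagged extras so the ingest
filters can be scored against ground truth.

Count process
-------------
Counts stay non-negative integers by working on the log scale:

    log mu_t = log(r) + sum_i a_i (log1p(y_{t-i}) - log1p(r))
                      + b (log1p(x_{t-L}) - log1p(r_x))
    y_t ~ Poisson(mu_t)

where r is the stream's base monthly rate. With b = 0 the two streams are
independent given their own histories; with b > 0 the regulatory stream
responds to social-media activity L months earlier, which is the
Granger-detectable signal recovered downstream. A 24-month burn-in is
discarded so the retained window starts near stationarity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .timeseries import CountSeries
from .vocab import TermHierarchy, default_vocabulary

BURN_IN_MONTHS = 24
_LOG_MEAN_CAP = math.log(1e6)

# Category weights patterned on the observed top-20 tables (relative
# frequencies; normalised at draw time). Regulatory weights carry a tail of
# lower-frequency HLTs so that stream is less concentrated than the reviews.
ATORVASTATIN_SM_WEIGHTS = {
    "Muscle or bone pain": 58.3, "Joint pain": 28.1, "Low energy": 26.4,
    "Mental fog or memory loss": 18.8, "Cramps": 15.7,
    "Stomach or bowel issues": 12.4, "Weakness": 11.2, "Depression": 10.4,
    "Insomnia": 10.3, "Numbness": 9.0, "Headache": 7.6, "Vertigo": 7.5,
    "Heart issue or chest pain": 6.3, "Blurry vision": 5.8, "Swelling": 4.9,
    "Skin issue": 3.8, "Anxiety": 3.5, "Urinary issue": 3.5,
    "Flu symptoms": 3.3, "Mood swings": 3.3,
}
ATORVASTATIN_REG_WEIGHTS = {
    "Muscle pains": 12.4, "Asthenic conditions": 11.2,
    "Musculoskeletal and connective tissue pain and discomfort": 9.8,
    "Diabetes mellitus (incl subtypes)": 9.4, "Liver function analyses": 8.0,
    "Muscle related signs and symptoms NEC": 7.4, "Pain and discomfort NEC": 6.9,
    "Cholesterol analyses": 5.6, "Joint related signs and symptoms": 5.4,
    "Myopathies": 5.3, "General signs and symptoms NEC": 5.0,
    "Skeletal and cardiac muscle analyses": 4.3, "Gait disturbances": 4.1,
    "Ischaemic coronary artery disorders": 4.1, "Muscle weakness conditions": 4.0,
    "Physical examination procedures and organ system status": 3.8,
    "Therapeutic and nontherapeutic responses": 3.5,
    "Paraesthesias and dysaesthesias": 3.4, "Death and sudden death": 3.4,
    "Nausea and vomiting symptoms": 3.2,
    # tail
    "Headaches NEC": 2.5, "Memory loss (excl dementia)": 2.2,
    "Cardiac signs and symptoms NEC": 2.0, "Anxiety symptoms": 2.0,
    "Depressive disorders": 2.0, "Neurological signs and symptoms NEC": 2.0,
    "Disturbances in initiating and maintaining sleep": 2.0,
    "Oedema NEC": 1.8, "Feelings and sensations NEC": 1.5,
    "Breathing abnormalities": 1.5, "Vascular tests NEC (incl blood pressure)": 1.5,
    "Heart rate and pulse investigations": 1.2,
    "Gastrointestinal atonic and hypomotility disorders NEC": 1.2,
    "Central nervous system haemorrhages and cerebrovascular accidents": 1.0,
    "Vascular hypertensive disorders": 1.0, "Appetite disorders": 1.0,
    "Oral dryness and saliva altered": 0.8,
}
SIBUTRAMINE_SM_WEIGHTS = {
    "Dry mouth": 37.4, "Headaches": 35.6, "Insomnia": 30.7,
    "Constipation": 16.3, "Cardiac symptoms": 14.1,
    "Anxiety or irritability": 14.1, "Lack of efficacy": 7.4,
    "Nausea or indigestion": 7.0, "Excessive thirst": 5.9, "Low energy": 5.6,
    "Muscle or joint pain": 5.6, "Hypertension": 4.8, "Bad breath": 3.0,
    "Depression": 2.6, "Sexual dysfunction": 2.6, "Sweating": 1.9,
    "Skin lesions": 1.5, "Shortness of breath": 0.7,
}
SIBUTRAMINE_REG_WEIGHTS = {
    "Therapeutic and nontherapeutic responses": 11.4, "Appetite disorders": 11.0,
    "Headaches NEC": 9.8, "Disturbances in initiating and maintaining sleep": 8.6,
    "General signs and symptoms NEC": 7.3, "Asthenic conditions": 7.1,
    "Vascular tests NEC (incl blood pressure)": 6.9,
    "Nausea and vomiting symptoms": 6.4, "Anxiety symptoms": 6.3,
    "Oral dryness and saliva altered": 5.9,
    "Neurological signs and symptoms NEC": 5.8, "Feelings and sensations NEC": 5.6,
    "Gastrointestinal atonic and hypomotility disorders NEC": 5.3,
    "Disturbances in consciousness NEC": 5.2, "Pain and discomfort NEC": 4.9,
    "Breathing abnormalities": 4.4, "Cardiac signs and symptoms NEC": 4.1,
    "Physical examination procedures and organ system status": 3.7,
    "Heart rate and pulse investigations": 3.5,
    "Paraesthesias and dysaesthesias": 3.3,
    # tail
    "Rate and rhythm disorders NEC": 1.8, "Ischaemic coronary artery disorders": 2.0,
    "Depressive disorders": 2.0, "Vascular hypertensive disorders": 1.5,
    "Central nervous system haemorrhages and cerebrovascular accidents": 1.5,
    "Muscle pains": 1.5, "Joint related signs and symptoms": 1.2,
    "Sexual desire disorders": 1.0, "Death and sudden death": 1.0,
    "Memory loss (excl dementia)": 0.8,
}

_PAIN_REG_HLTS = frozenset(
    {
        "Muscle pains",
        "Musculoskeletal and connective tissue pain and discomfort",
        "Pain and discomfort NEC",
    }
)
_CV_REG_HLTS = frozenset(
    {
        "Cardiac signs and symptoms NEC",
        "Rate and rhythm disorders NEC",
        "Ischaemic coronary artery disorders",
        "Vascular hypertensive disorders",
        "Central nervous system haemorrhages and cerebrovascular accidents",
    }
)


def _normalise(weights: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterisation of one paired-stream simulation.

    Rates are expected reports per calendar month; ages in years;
    ``true_lag`` is the lead (months) of the social-media series over the
    regulatory series when ``coupling_coeff`` is nonzero.
    """

    drug: str
    n_months: int
    ae_probs_sm: Mapping[str, float]
    ae_probs_reg: Mapping[str, float]
    start_month: str = "2001-06"
    base_rate_sm: float = 5.0
    base_rate_reg: float = 40.0
    self_coeffs_sm: tuple[float, ...] = (0.5,)
    self_coeffs_reg: tuple[float, ...] = (0.25,)
    coupling_coeff: float = 0.0
    true_lag: int = 4
    p_serious_sm: Mapping[str, float] = field(default_factory=dict)
    p_serious_reg: Mapping[str, float] = field(default_factory=dict)
    age_mean_sm: float = 36.8
    age_sd_sm: float = 10.1
    age_mean_reg: float = 43.8
    age_sd_reg: float = 13.5
    p_female_sm: float = 0.885
    p_female_reg: float = 0.86
    rating_mean: float = 4.0
    rating_sd: float = 1.1
    rating_shift: float = 0.6
    specific_categories: tuple[str, ...] = ()
    p_extra_category: float = 0.3
    hearsay_frac: float = 0.05
    insufficient_frac: float = 0.03
    duplicate_frac: float = 0.03
    nonprimary_frac: float = 0.05
    trial_literature_frac: float = 0.05
    p_age_missing: float = 0.05
    p_gender_missing: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_months < 2 * (self.true_lag + 1):
            raise ValueError(
                f"n_months={self.n_months} below identifiability floor "
                f"{2 * (self.true_lag + 1)} for true_lag={self.true_lag}"
            )
        if self.true_lag < 1:
            raise ValueError("true_lag must be a positive integer")
        if self.base_rate_sm < 0 or self.base_rate_reg < 0:
            raise ValueError("base rates must be non-negative")
        if self.age_sd_sm <= 0 or self.age_sd_reg <= 0:
            raise ValueError("age_sd must be positive")
        for name, probs in (("ae_probs_sm", self.ae_probs_sm), ("ae_probs_reg", self.ae_probs_reg)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name in (
            "p_female_sm", "p_female_reg", "p_extra_category", "hearsay_frac",
            "insufficient_frac", "duplicate_frac", "nonprimary_frac",
            "trial_literature_frac", "p_age_missing", "p_gender_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, probs in (("p_serious_sm", self.p_serious_sm), ("p_serious_reg", self.p_serious_reg)):
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def preset_config(drug: str, **overrides) -> SimulationConfig:
    """Study-condition presets for the two drug archetypes.

    ``atorvastatin``: older reporters, balanced gender, musculoskeletal
    AE mixture, low overall satisfaction, no lead-lag coupling by default
    (the null archetype). ``sibutramine``: younger, predominantly female
    reporters, cardiometabolic AE mixture, higher satisfaction, and a
    lag-4 coupling by default (the coupled archetype).
    """
    if drug == "atorvastatin":
        base = dict(
            drug=drug,
            n_months=164,
            start_month="2001-04",
            base_rate_sm=6.0,
            base_rate_reg=120.0,
            coupling_coeff=0.0,
            true_lag=4,
            ae_probs_sm=_normalise(ATORVASTATIN_SM_WEIGHTS),
            ae_probs_reg=_normalise(ATORVASTATIN_REG_WEIGHTS),
            p_serious_sm={c: (0.025 if c in ("Muscle or bone pain", "Joint pain", "Cramps", "Headache", "Heart issue or chest pain") else 0.02) for c in ATORVASTATIN_SM_WEIGHTS},
            p_serious_reg={h: (0.382 if h in _PAIN_REG_HLTS else 0.20) for h in ATORVASTATIN_REG_WEIGHTS},
            age_mean_sm=53.9, age_sd_sm=10.8, age_mean_reg=64.0, age_sd_reg=12.7,
            p_female_sm=0.482, p_female_reg=0.533,
            rating_mean=2.3, rating_sd=1.3, rating_shift=0.4,
            specific_categories=("Muscle or bone pain", "Joint pain", "Cramps", "Headache", "Heart issue or chest pain"),
        )
    elif drug == "sibutramine":
        base = dict(
            drug=drug,
            n_months=137,
            start_month="2001-06",
            base_rate_sm=2.0,
            base_rate_reg=38.0,
            coupling_coeff=0.8,
            true_lag=4,
            ae_probs_sm=_normalise(SIBUTRAMINE_SM_WEIGHTS),
            ae_probs_reg=_normalise(SIBUTRAMINE_REG_WEIGHTS),
            p_serious_sm={c: (0.079 if c == "Cardiac symptoms" else 0.02) for c in SIBUTRAMINE_SM_WEIGHTS},
            p_serious_reg={h: (0.63 if h in _CV_REG_HLTS else 0.25) for h in SIBUTRAMINE_REG_WEIGHTS},
            age_mean_sm=36.8, age_sd_sm=10.1, age_mean_reg=43.8, age_sd_reg=13.5,
            p_female_sm=0.885, p_female_reg=0.86,
            rating_mean=4.1, rating_sd=1.0, rating_shift=0.6,
            specific_categories=("Cardiac symptoms",),
        )
    else:
        raise ValueError(f"unknown preset drug {drug!r}")
    base.update(overrides)
    return SimulationConfig(**base)


def _simulate_log_linear(
    rng: np.random.Generator,
    n_keep: int,
    base_sm: float,
    base_reg: float,
    a_sm: tuple[float, ...],
    a_reg: tuple[float, ...],
    beta: float,
    lag: int,
) -> tuple[np.ndarray, np.ndarray]:
    warm = max(len(a_sm), len(a_reg), lag, 1)
    total = BURN_IN_MONTHS + warm + n_keep
    y_sm = np.zeros(total)
    y_reg = np.zeros(total)
    g_sm = math.log1p(base_sm)
    g_reg = math.log1p(base_reg)
    for t in range(total):
        if t < warm:
            y_sm[t] = rng.poisson(base_sm) if base_sm > 0 else 0
            y_reg[t] = rng.poisson(base_reg) if base_reg > 0 else 0
            continue
        if base_sm > 0:
            eta = math.log(base_sm) + sum(
                a * (math.log1p(y_sm[t - i - 1]) - g_sm) for i, a in enumerate(a_sm)
            )
            y_sm[t] = rng.poisson(math.exp(min(eta, _LOG_MEAN_CAP)))
        if base_reg > 0:
            eta = math.log(base_reg) + sum(
                a * (math.log1p(y_reg[t - i - 1]) - g_reg) for i, a in enumerate(a_reg)
            )
            eta += beta * (math.log1p(y_sm[t - lag]) - g_sm)
            y_reg[t] = rng.poisson(math.exp(min(eta, _LOG_MEAN_CAP)))
    keep = slice(total - n_keep, total)
    return y_sm[keep].astype(int), y_reg[keep].astype(int)


def simulate_count_pair(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Simulate the paired monthly count processes.

    Returns ``(sm, reg, truth)`` where the first two are
    :class:`~aelead.timeseries.CountSeries` and ``truth`` records the
    generative lead-lag parameters for recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sm_vals, reg_vals = _simulate_log_linear(
        rng,
        config.n_months,
        config.base_rate_sm,
        config.base_rate_reg,
        config.self_coeffs_sm,
        config.self_coeffs_reg,
        config.coupling_coeff,
        config.true_lag,
    )
    idx = pd.period_range(config.start_month, periods=config.n_months, freq="M")
    sm = CountSeries(pd.Series(sm_vals, index=idx), stream="social_media")
    reg = CountSeries(pd.Series(reg_vals, index=idx), stream="regulatory")
    truth = {"true_lag": config.true_lag, "beta": config.coupling_coeff}
    return sm, reg, truth


# --------------------------------------------------------------------------
# record-level disaggregation


def _trunc_normal(rng, mean, sd, lo=18.0, hi=100.0) -> float:
    # draw-and-reject keeps the exact truncated-normal law
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def _draw_categories(rng, labels, probs, p_extra, max_cats=3) -> list[str]:
    cats = [labels[rng.choice(len(labels), p=probs)]]
    while len(cats) < max_cats and rng.random() < p_extra:
        extra = labels[rng.choice(len(labels), p=probs)]
        if extra not in cats:
            cats.append(extra)
    return cats


_SERIOUS_COMMENT = "ended up in the hospital for several days"
_MILD_COMMENT = "manageable so far"
_HEARSAY_COMMENT = "my friend said the same thing happened to them"
_INSUFFICIENT_TEXT = "none that i can say"


def simulate_reports(
    config: SimulationConfig,
    counts_sm: CountSeries,
    counts_reg: CountSeries,
    rng: np.random.Generator | None = None,
    vocab: TermHierarchy | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disaggregate monthly counts into individual report rows.

    Exactly ``counts[t]`` analysable records are emitted per stream per
    month; junk records (hearsay / insufficient / duplicate reviews,
    non-primary-suspect or trial/literature regulatory reports) are
    injected on top and flagged in the hidden ``truth_exclude`` column so
    filter accuracy can be scored exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if vocab is None:
        vocab = default_vocabulary(config.drug)
    if (counts_sm.to_numpy() < 0).any() or (counts_reg.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    sm_labels = list(config.ae_probs_sm)
    sm_probs = np.array([config.ae_probs_sm[c] for c in sm_labels])
    reg_labels = list(config.ae_probs_reg)
    reg_probs = np.array([config.ae_probs_reg[c] for c in reg_labels])
    for h in reg_labels:
        if not vocab.pts_in_hlt(h):
            raise ValueError(f"regulatory category {h!r} has no PTs in the hierarchy")

    reviews: list[dict] = []
    rid = 0

    def _review_row(month: pd.Period, exclude: str = "") -> dict:
        nonlocal rid
        rid += 1
        day = int(rng.integers(1, month.days_in_month + 1))
        cats = _draw_categories(rng, sm_labels, sm_probs, config.p_extra_category)
        # a report is serious if any of its AEs is
        p_ser = max(config.p_serious_sm.get(c, 0.02) for c in cats)
        serious = bool(rng.random() < p_ser)
        specific = any(c in config.specific_categories for c in cats)
        phrases = [
            vocab.lexicon[c][int(rng.integers(len(vocab.lexicon[c])))] for c in cats
        ]
        side_effects = ", ".join(phrases)
        comments = _SERIOUS_COMMENT if serious else _MILD_COMMENT
        latent = (
            config.rating_mean
            - config.rating_shift * specific
            - config.rating_shift * serious
            + rng.normal(0.0, config.rating_sd)
        )
        rating = int(min(5, max(1, round(latent))))
        age = _trunc_normal(rng, config.age_mean_sm, config.age_sd_sm)
        if rng.random() < config.p_age_missing:
            age = np.nan
        gender = "F" if rng.random() < config.p_female_sm else "M"
        if rng.random() < config.p_gender_missing:
            gender = ""
        return {
            "record_id": f"R{rid:06d}",
            "post_date": f"{month.year:04d}-{month.month:02d}-{day:02d}",
            "age": age,
            "gender": gender,
            "drug": config.drug,
            "dosage": f"{int(rng.choice([5, 10, 15, 20, 40]))} mg",
            "rating": rating,
            "side_effects": side_effects,
            "comments": comments,
            "truth_categories": ";".join(cats),
            "truth_serious": int(serious),
            "truth_exclude": exclude,
        }

    for month, n in zip(counts_sm.values.index, counts_sm.to_numpy().astype(int)):
        clean_start = len(reviews)
        for _ in range(n):
            reviews.append(_review_row(month))
        clean_rows = reviews[clean_start:]
        for _ in range(int(rng.binomial(n, config.hearsay_frac))):
            row = _review_row(month, exclude="hearsay")
            row["comments"] = _HEARSAY_COMMENT
            reviews.append(row)
        for _ in range(int(rng.binomial(n, config.insufficient_frac))):
            row = _review_row(month, exclude="insufficient")
            row["side_effects"] = _INSUFFICIENT_TEXT
            row["comments"] = ""
            reviews.append(row)
        # duplicates copy rows with known age and gender, matching the
        # ingest rule that an "obvious" duplicate needs a comparable key
        candidates = [r for r in clean_rows if r["age"] == r["age"] and r["gender"]]
        if candidates:
            for _ in range(int(rng.binomial(n, config.duplicate_frac))):
                src = candidates[int(rng.integers(len(candidates)))]
                rid += 1
                dup = dict(src)
                dup["record_id"] = f"R{rid:06d}"
                dup["truth_exclude"] = "duplicate"
                reviews.append(dup)

    reports: list[dict] = []

    def _report_row(month: pd.Period, exclude: str = "") -> dict:
        nonlocal rid
        rid += 1
        day = int(rng.integers(1, month.days_in_month + 1))
        cats = _draw_categories(rng, reg_labels, reg_probs, config.p_extra_category)
        pts = []
        for c in cats:
            options = vocab.pts_in_hlt(c)
            pts.append(options[int(rng.integers(len(options)))])
        serious = bool(
            rng.random() < max(config.p_serious_reg.get(c, 0.25) for c in cats)
        )
        age = _trunc_normal(rng, config.age_mean_reg, config.age_sd_reg)
        if rng.random() < config.p_age_missing:
            age = np.nan
        gender = "F" if rng.random() < config.p_female_reg else "M"
        if rng.random() < config.p_gender_missing:
            gender = ""
        if exclude == "drug_role":
            role = str(rng.choice(["secondary_suspect", "concomitant", "interacting"]))
            source = "consumer"
        elif exclude == "source":
            role = "primary_suspect"
            source = str(rng.choice(["clinical_trial", "literature"]))
        else:
            role = "primary_suspect"
            source = "consumer" if rng.random() < 0.6 else "health_professional"
        return {
            "record_id": f"F{rid:06d}",
            "fda_date": f"{month.year:04d}-{month.month:02d}-{day:02d}",
            "age": age,
            "gender": gender,
            "drug": config.drug,
            "drug_role": role,
            "report_source": source,
            "pt_terms": ";".join(pts),
            "serious": int(serious),
            "truth_categories": ";".join(cats),
            "truth_exclude": exclude,
        }

    for month, n in zip(counts_reg.values.index, counts_reg.to_numpy().astype(int)):
        for _ in range(n):
            reports.append(_report_row(month))
        for _ in range(int(rng.binomial(n, config.nonprimary_frac))):
            reports.append(_report_row(month, exclude="drug_role"))
        for _ in range(int(rng.binomial(n, config.trial_literature_frac))):
            reports.append(_report_row(month, exclude="source"))

    review_cols = [
        "record_id", "post_date", "age", "gender", "drug", "dosage", "rating",
        "side_effects", "comments", "truth_categories", "truth_serious",
        "truth_exclude",
    ]
    report_cols = [
        "record_id", "fda_date", "age", "gender", "drug", "drug_role",
        "report_source", "pt_terms", "serious", "truth_categories",
        "truth_exclude",
    ]
    reviews_df = pd.DataFrame(reviews, columns=review_cols)
    reports_df = pd.DataFrame(reports, columns=report_cols)
    return reviews_df, reports_df


def write_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Simulate and write the two report CSVs plus the ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sm, reg, truth = simulate_count_pair(config)
    reviews, reports = simulate_reports(config, sm, reg)
    paths = {
        "reviews": outdir / "reviews.csv",
        "reports": outdir / "reports.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    reviews.to_csv(paths["reviews"], index=False)
    reports.to_csv(paths["reports"], index=False)
    gt = pd.DataFrame(
        {
            "month": sm.values.index.astype(str),
            "sm_count": sm.to_numpy().astype(int),
            "reg_count": reg.to_numpy().astype(int),
            "true_lag": truth["true_lag"],
            "beta": truth["beta"],
        }
    )
    gt.to_csv(paths["ground_truth"], index=False)
    return paths
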