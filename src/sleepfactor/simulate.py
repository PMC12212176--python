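"""Synthetic oncology sleep-questionnaire cohorts with known ground truth.

Each patient carries two latent traits on the logit scale: night-time
sleep disruption (theta_SQ) and daytime sleepiness (theta_DTS), drawn
from a bivariate normal that is uncorrelated by default (the two scores
were found to vary independently).  MOS-SS item responses are generated
from the partial credit model on the item's own trait, EORTC items
10/18 load on the sleepiness trait and item 11 on the sleep-quality
trait, the anamnesis good/poor-sleep label and sleep-medication use are
thresholded noisy functions of theta_SQ, women receive a negative shift
on theta_DTS only, and biomarker columns are log-normal draws with no
association to either trait.  Follow-up traits are baseline plus a
small drift and independent noise, so per-patient changes in the two
scores are uncorrelated by construction.

The generated record table has the same schema as a real cohort CSV;
the ground-truth traits are kept in a separate table so pipeline code
can never read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .instruments import DTS_ITEMS, SQ_ITEMS
from .rasch import PcmItem, pcm_probability

#: items whose raw rank is already worst-high (no reversal in scoring)
_WORST_HIGH = frozenset({1, 2, 4, 12})

BIOMARKER_DEFAULTS: dict[str, tuple[float, float]] = {
    # name -> (log-mean, log-sd); levels are arbitrary assay units
    "melatonin_creatinine": (2.5, 0.8),
    "cortisol_creatinine": (2.0, 0.7),
    "crp": (1.0, 1.0),
    "il2": (0.5, 0.6),
    "bmal1": (0.0, 0.5),
    "per2": (0.0, 0.5),
}

TUMOUR_GROUPS = ("colorectal", "gastric", "urothelial", "breast", "other")
TUMOUR_PROBS = (0.41, 0.25, 0.15, 0.15, 0.04)


def default_item_params() -> dict[int, tuple[str, PcmItem]]:
    """Generative PCM parameters for MOS items 1-12.

    Item locations sit above zero so that, with traits centred at zero,
    most responses fall in the low-disruption categories (the marginal
    skew typical of these cohorts).  Thresholds are ordered and vary a
    little across items.  Factor membership follows the SQ/DTS split;
    items 1 and 2 ride on the sleep-quality trait but never enter the
    scores.
    """
    base_tau = np.array([-1.6, -0.5, 0.5, 1.6])
    spec: dict[int, tuple[str, float, np.ndarray]] = {}
    deltas = {1: 0.8, 2: 0.6, 3: 0.9, 4: 0.5, 5: 1.4, 6: 0.7, 7: 0.8,
              8: 0.6, 9: 1.1, 10: 1.0, 11: 0.6, 12: 0.5}
    jitter = {1: 0.0, 2: 0.1, 3: -0.1, 4: 0.2, 5: 0.1, 6: 0.0, 7: -0.2,
              8: 0.0, 9: 0.1, 10: -0.1, 11: 0.2, 12: 0.0}
    for i in range(1, 13):
        if i in SQ_ITEMS or i in (1, 2):
            trait = "sq"
        elif i in DTS_ITEMS:
            trait = "dts"
        spec[i] = (trait, deltas[i], base_tau * (1.0 + jitter[i]))
    return {
        i: (trait, PcmItem(item_id=i, m=4, delta=d, tau=tau - tau.mean()))
        for i, (trait, d, tau) in spec.items()
    }


@dataclass
class GeneratorConfig:
    """Study-structure parameters of the synthetic cohort generator."""

    n_patients: int = 90
    #: patients who complete every questionnaire item at both timepoints
    n_questionnaire_complete: int = 75
    #: questionnaire-completers who also have full biomarker panels
    n_biomarker_complete: int = 54
    trait_corr: float = 0.0
    #: SD of each latent trait in logits; sets item intercorrelation strength
    trait_sd: float = 1.4
    item_params: dict[int, tuple[str, PcmItem]] = field(default_factory=default_item_params)
    #: additive shift of theta_DTS for women (logits; negative = less sleepy)
    sex_effect_dts: float = -1.6
    p_female: float = 0.37
    #: anamnesis poor-sleep label: theta_SQ + noise over its 75th percentile
    anamnesis_noise_sd: float = 1.3
    anamnesis_quantile: float = 0.75
    #: EORTC items: trait driving each, and marginal cumulative proportions
    eortc_traits: dict[int, str] = field(
        default_factory=lambda: {10: "dts", 11: "sq", 18: "dts"}
    )
    eortc_cum_props: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            10: (0.21, 0.71, 0.97),
            11: (0.48, 0.85, 0.97),
            18: (0.15, 0.70, 0.97),
        }
    )
    eortc_noise_sd: float = 0.8
    #: sleep medication (0 none / 1 as-needed / 2 daily) from theta_SQ
    medication_cum_props: tuple[float, float] = (0.76, 0.88)
    medication_noise_sd: float = 1.3
    biomarker_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BIOMARKER_DEFAULTS)
    )
    #: mean trait drift baseline -> follow-up (logits)
    followup_shift_sq: float = 0.0
    followup_shift_dts: float = -0.45
    followup_noise_sd: float = 1.0
    #: extra fully-at-random per-item missingness on top of the attrition model
    missing_rate: float = 0.0
    p_adjuvant: float = 0.36
    seed: int = 0

    @classmethod
    def scaled(cls, n_patients: int, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Config for an arbitrary cohort size with the default attrition
        fractions (75/90 questionnaire-complete, 54/90 biomarker-complete)."""
        overrides.setdefault("n_questionnaire_complete", round(n_patients * 75 / 90))
        overrides.setdefault("n_biomarker_complete", round(n_patients * 54 / 90))
        return cls(n_patients=n_patients, seed=seed, **overrides)

    def __post_init__(self) -> None:
        if not (-1.0 < self.trait_corr < 1.0):
            raise ValueError("|trait_corr| must be below 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0 <= self.n_biomarker_complete <= self.n_questionnaire_complete
                <= self.n_patients):
            raise ValueError(
                "need n_biomarker_complete <= n_questionnaire_complete <= n_patients"
            )
        for i, (trait, item) in self.item_params.items():
            if trait not in ("sq", "dts"):
                raise ValueError(f"item {i}: unknown trait {trait!r}")
            if item.item_id != i:
                raise ValueError(f"item_params key {i} does not match item_id {item.item_id}")


@dataclass
class SyntheticCohort:
    """Generated records plus the ground truth that produced them."""

    records: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def generate_responses(theta, item: PcmItem, rng: np.random.Generator,
                       worst_high: bool = False) -> np.ndarray:
    """Sample MOS ranks 1..5 from the partial credit model.

    Severity categories 0..m are drawn from ``pcm_probability`` at the
    given trait value(s), then mapped to the instrument's rank coding:
    ``rank = severity + 1`` for worst-high items (1, 2, 4, 12) and
    ``rank = 5 - severity`` for the reversed (negative) items, so that
    scoring the generated data makes high theta mean worse sleep.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    probs = pcm_probability(theta, item)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(theta.shape[0])
    severity = (cum < u[:, None]).sum(axis=1)
    if worst_high:
        return severity + 1
    return item.m + 1 - severity


def _graded_from_trait(z: np.ndarray, cum_props, rng: np.random.Generator,
                       noise_sd: float) -> np.ndarray:
    """Ordinal categories 1..k+1 by thresholding z + noise at normal quantiles."""
    from scipy.special import ndtri

    total_sd = np.sqrt(1.0 + noise_sd**2)
    cuts = ndtri(np.asarray(cum_props)) * total_sd
    latent = z + rng.normal(0.0, noise_sd, z.shape)
    return 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate one cohort; deterministic for a fixed config and seed."""
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    sd = cfg.trait_sd

    cov = sd**2 * np.array([[1.0, cfg.trait_corr], [cfg.trait_corr, 1.0]])
    theta_bl = rng.multivariate_normal([0.0, 0.0], cov, size=n)  # cols: sq, dts
    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    theta_bl[:, 1] += np.where(sex == "female", cfg.sex_effect_dts, 0.0)
    drift = np.array([cfg.followup_shift_sq, cfg.followup_shift_dts])
    theta_fu = theta_bl + drift + rng.normal(0.0, cfg.followup_noise_sd, (n, 2))

    age = rng.integers(31, 83, n)
    bmi = np.clip(rng.normal(26.0, 4.0, n), 19.0, 43.0).round(1)
    intent = np.where(rng.random(n) < cfg.p_adjuvant, "adjuvant", "palliative")
    tumour = rng.choice(TUMOUR_GROUPS, size=n, p=TUMOUR_PROBS)
    pid = np.array([f"P{i + 1:03d}" for i in range(n)])

    # attrition structure: who is questionnaire-incomplete / biomarker-missing
    order = rng.permutation(n)
    incomplete = np.zeros(n, dtype=bool)
    incomplete[order[cfg.n_questionnaire_complete:]] = True
    completers = order[: cfg.n_questionnaire_complete]
    bio_missing = np.zeros(n, dtype=bool)
    bio_missing[incomplete] = True
    bio_missing[completers[cfg.n_biomarker_complete:]] = True

    frames = []
    for tp, theta in (("baseline", theta_bl), ("followup", theta_fu)):
        row: dict[str, object] = {
            "patient_id": pid,
            "timepoint": tp,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "treatment_intent": intent,
            "tumour_group": tumour,
        }
        for i in range(1, 13):
            trait, item = cfg.item_params[i]
            th = theta[:, 0] if trait == "sq" else theta[:, 1]
            row[f"mos_q{i}"] = generate_responses(th, item, rng,
                                                  worst_high=i in _WORST_HIGH).astype(float)
        for q in (10, 11, 18):
            trait = cfg.eortc_traits[q]
            z = (theta[:, 0] if trait == "sq" else theta[:, 1]) / sd
            row[f"eortc_q{q}"] = _graded_from_trait(
                z, cfg.eortc_cum_props[q], rng, cfg.eortc_noise_sd
            ).astype(float)
        from scipy.special import ndtri

        ana_cut = ndtri(cfg.anamnesis_quantile) * np.sqrt(sd**2 + cfg.anamnesis_noise_sd**2)
        ana_latent = theta[:, 0] + rng.normal(0.0, cfg.anamnesis_noise_sd, n)
        row["anamnesis_sleep"] = (ana_latent > ana_cut).astype(float)
        med_latent = theta[:, 0] / sd
        row["sleep_med"] = (
            _graded_from_trait(med_latent, cfg.medication_cum_props, rng,
                               cfg.medication_noise_sd / sd) - 1
        ).astype(float)
        for name, (mu, sig) in cfg.biomarker_model.items():
            row[f"biomarker_{name}"] = np.round(rng.lognormal(mu, sig, n), 4)
        frames.append(pd.DataFrame(row))

    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["patient_id", "timepoint"], kind="stable").reset_index(
        drop=True
    )

    item_cols = [f"mos_q{i}" for i in range(1, 13)] + [f"eortc_q{q}" for q in (10, 11, 18)]
    # questionnaire-incomplete patients lose a random subset of items
    for p in pid[incomplete]:
        mask = records["patient_id"] == p
        idx = records.index[mask]
        drop = rng.random((idx.size, len(item_cols))) < 0.15
        if not drop.any():
            drop[rng.integers(idx.size), rng.integers(len(item_cols))] = True
        for r, ridx in enumerate(idx):
            for c, col in enumerate(item_cols):
                if drop[r, c]:
                    records.loc[ridx, col] = np.nan
    bio_cols = [c for c in records.columns if c.startswith("biomarker_")]
    records.loc[records["patient_id"].isin(pid[bio_missing]), bio_cols] = np.nan
    if cfg.missing_rate > 0:
        for col in item_cols:
            hit = rng.random(len(records)) < cfg.missing_rate
            records.loc[hit, col] = np.nan

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "theta_sq_baseline": theta_bl[:, 0],
            "theta_dts_baseline": theta_bl[:, 1],
            "theta_sq_followup": theta_fu[:, 0],
            "theta_dts_followup": theta_fu[:, 1],
            "sex": sex,
            "questionnaire_incomplete": incomplete,
            "biomarker_missing": bio_missing,
        }
    )
    return SyntheticCohort(records=records, truth=truth, config=cfg)


def severity_matrix(records: pd.DataFrame, items, timepoint: str = "baseline") -> pd.DataFrame:
    """Problem-oriented category scores 0..4 for the given MOS items.

    Reverses the rank coding back to severities (input for the Rasch
    stage): reversed items give ``5 - rank``, worst-high items
    ``rank - 1``.  Missing responses stay NaN.
    """
    sub = records[records["timepoint"] == timepoint] if "timepoint" in records.columns \
        else records
    out = {}
    for i in items:
        r = sub[f"mos_q{i}"].to_numpy(dtype=float)
        out[f"mos_q{i}"] = r - 1 if i in _WORST_HIGH else 5 - r
    df = pd.DataFrame(out)
    if "patient_id" in sub.columns:
        df.index = pd.Index(sub["patient_id"], name="patient_id")
    return df
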