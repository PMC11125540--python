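"""Parameter containers for the microsimulation.

All disease, procedure, cost and demographic inputs are held in plain
dataclasses whose fields are numpy arrays indexed by sex and/or quarter of
age.  Time is discrete: 3-month increments from birth (quarter 0) to age 100
(quarter 400); nobody survives past quarter 400.

Every container supports a lossless ``to_dict``/``from_dict`` round trip so
bundles can be stored as YAML/JSON config files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

#: quarters per year and hard age cap (100 years).
QPY = 4
MAX_Q = 400

#: colon segments ordered proximal (cecum) to distal (rectum).
SEGMENTS = (
    "cecum",
    "ascending",
    "hepatic_flexure",
    "transverse",
    "splenic_flexure",
    "descending",
    "sigmoid",
    "rectum",
)
N_SEGMENTS = len(SEGMENTS)

#: scope-insertion depth ("reach level") needed to visualize each segment:
#: 0 = rectum..descending (always seen), 1 = past splenic flexure,
#: 2 = past hepatic flexure, 3 = cecum reached.
SEGMENT_REACH_LEVEL = np.array([3, 2, 2, 1, 1, 0, 0, 0], dtype=np.int64)

#: proximal ("right colon") segments for the direct-path location preference.
RIGHT_COLON = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.float64)

SEXES = ("female", "male")

N_ADENOMA_STAGES = 6
N_CANCER_STAGES = 4
#: adenoma stages 1..EARLY_ADVANCED_BOUNDARY are "early", above are "advanced"
EARLY_ADVANCED_BOUNDARY = 4
#: CRC death can only occur within this many quarters of cancer initiation.
CRC_DEATH_WINDOW_Q = 20


class ValidationError(ValueError):
    """Raised when a parameter container violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _interp_by_age(knot_ages: Sequence[float], knot_values: Sequence[float]) -> np.ndarray:
    """Piecewise-linear interpolation of an age-indexed quantity onto quarters."""
    ages_q = (np.arange(MAX_Q) + 0.5) / QPY
    return np.interp(ages_q, np.asarray(knot_ages, float), np.asarray(knot_values, float))


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Per-quarter probability of death from non-CRC causes, by sex.

    ``q[sex, quarter]`` is the probability of dying of other causes within
    that quarter conditional on being alive at its start.  The final quarter
    is forced to 1 so that nobody survives past age 100.
    """

    q: np.ndarray  # shape (2, MAX_Q), rows follow SEXES order

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        _check(self.q.shape == (2, MAX_Q), f"life table must be (2, {MAX_Q})")
        _check(np.all((self.q >= 0) & (self.q <= 1)), "q outside [0, 1]")
        _check(np.allclose(self.q[:, -1], 1.0), "final-quarter q must equal 1")
        over30 = self.q[:, 30 * QPY:]
        _check(np.all(np.diff(over30, axis=1) >= -1e-12), "q must be non-decreasing above age 30")

    def death_quarter_pmf(self, sex: int) -> np.ndarray:
        """Distribution of the quarter of death; sums to 1 exactly (last q is 1)."""
        q = self.q[sex]
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
        return surv * q

    def sample_death_quarter(self, sex: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorized inverse-CDF sampling of the other-cause death quarter."""
        out = np.empty(sex.shape[0], dtype=np.int64)
        for s in (0, 1):
            mask = sex == s
            if not np.any(mask):
                continue
            cdf = np.cumsum(self.death_quarter_pmf(s))
            cdf[-1] = 1.0
            u = rng.random(int(mask.sum()))
            out[mask] = np.searchsorted(cdf, u, side="right")
        return np.minimum(out, MAX_Q - 1)

    def to_dict(self) -> dict:
        return {"q": {sex: self.q[i].tolist() for i, sex in enumerate(SEXES)}}

    @classmethod
    def from_dict(cls, d: dict) -> "LifeTable":
        q = np.stack([np.asarray(d["q"][sex], float) for sex in SEXES])
        return cls(q=q)

    # CSV interface: columns sex, age_quarter, q
    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, sex in enumerate(SEXES):
            for aq in range(MAX_Q):
                rows.append((sex, aq, self.q[i, aq]))
        pd.DataFrame(rows, columns=["sex", "age_quarter", "q"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        q = np.zeros((2, MAX_Q))
        for i, sex in enumerate(SEXES):
            sub = df[df["sex"] == sex].sort_values("age_quarter")
            q[i] = sub["q"].to_numpy()
        return cls(q=q)


# ---------------------------------------------------------------------------
# Natural history
# ---------------------------------------------------------------------------


@dataclass
class NaturalHistoryParams:
    """All disease-process rates, per quarter unless stated otherwise."""

    # adenoma initiation hazard per quarter, shape (2, MAX_Q)
    adenoma_init_rate: np.ndarray
    # lognormal sigma of the mean-1 individual risk multiplier (0 = everyone 1)
    risk_heterogeneity_sigma: float
    # probability distribution over SEGMENTS for new adenomas
    location_distribution: np.ndarray
    # per-quarter probability of advancing adenoma stage s -> s+1, s = 1..5
    stage_progression_prob: np.ndarray
    # per-quarter probability of adenoma stage s -> preclinical cancer, s = 1..6
    adenoma_to_preclinical_prob: np.ndarray
    # hazard per quarter of cancer arising from normal mucosa, shape (2, MAX_Q)
    direct_path_rate: np.ndarray
    # multiplicative weight on proximal segments in the direct-path location draw
    direct_right_colon_weight: float
    # per-quarter probability of preclinical stage I->II, II->III, III->IV
    preclinical_stage_progression_prob: np.ndarray
    # per-quarter probability of symptomatic detection while in stage I..IV
    symptomatic_detection_prob: np.ndarray
    # distribution over stage I..IV at direct-path onset
    stage_at_direct_onset: np.ndarray
    # fraction surviving CRC by stage at diagnosis
    survival_5yr: np.ndarray
    # distribution of CRC death delay over quarters 1..20 after initiation
    crc_death_time_distribution: np.ndarray
    # lesion-level growth-rate mixture: each adenoma draws a speed factor
    # multiplying its stage-progression and malignant-transformation
    # probabilities (slow- and fast-growing lesions; degenerate {1: 1.0}
    # reproduces homogeneous growth)
    progression_speed_values: np.ndarray = None
    progression_speed_probs: np.ndarray = None
    # stages <= boundary are "early" adenomas; above, "advanced"
    early_advanced_boundary: int = EARLY_ADVANCED_BOUNDARY
    # anchor of the 5-year CRC death window: "initiation" (literal reading)
    # or "diagnosis" (survival statistics are diagnosis-based)
    death_window_anchor: str = "initiation"

    def __post_init__(self) -> None:
        for name in (
            "adenoma_init_rate",
            "location_distribution",
            "stage_progression_prob",
            "adenoma_to_preclinical_prob",
            "direct_path_rate",
            "preclinical_stage_progression_prob",
            "symptomatic_detection_prob",
            "stage_at_direct_onset",
            "survival_5yr",
            "crc_death_time_distribution",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.progression_speed_values is None:
            self.progression_speed_values = np.array([1.0])
        if self.progression_speed_probs is None:
            self.progression_speed_probs = np.array([1.0])
        self.progression_speed_values = np.asarray(self.progression_speed_values, float)
        self.progression_speed_probs = np.asarray(self.progression_speed_probs, float)
        self.validate()

    def validate(self) -> None:
        _check(self.adenoma_init_rate.shape == (2, MAX_Q), "adenoma_init_rate shape")
        _check(np.all(self.adenoma_init_rate >= 0), "initiation hazard < 0")
        _check(self.risk_heterogeneity_sigma >= 0, "risk sigma < 0")
        _check(self.location_distribution.shape == (N_SEGMENTS,), "location dist shape")
        _check(abs(self.location_distribution.sum() - 1) < 1e-9, "location dist must sum to 1")
        _check(np.all(self.location_distribution >= 0), "location dist < 0")
        _check(self.stage_progression_prob.shape == (5,), "stage progression shape")
        _check(self.adenoma_to_preclinical_prob.shape == (6,), "adenoma->cancer shape")
        _check(self.preclinical_stage_progression_prob.shape == (3,), "preclinical prog shape")
        _check(self.symptomatic_detection_prob.shape == (4,), "symptomatic detection shape")
        _check(self.stage_at_direct_onset.shape == (4,), "direct-onset stage shape")
        _check(abs(self.stage_at_direct_onset.sum() - 1) < 1e-9, "direct-onset dist sums to 1")
        _check(self.survival_5yr.shape == (4,), "survival shape")
        _check(self.crc_death_time_distribution.shape == (CRC_DEATH_WINDOW_Q,), "death-time shape")
        _check(abs(self.crc_death_time_distribution.sum() - 1) < 1e-9, "death-time dist sums to 1")
        for name in (
            "stage_progression_prob",
            "adenoma_to_preclinical_prob",
            "preclinical_stage_progression_prob",
            "symptomatic_detection_prob",
            "survival_5yr",
        ):
            a = getattr(self, name)
            _check(np.all((a >= 0) & (a <= 1)), f"{name} outside [0, 1]")
        _check(np.all(self.direct_path_rate >= 0), "direct-path hazard < 0")
        _check(self.progression_speed_values.shape == self.progression_speed_probs.shape,
               "speed mixture values/probs shape mismatch")
        _check(np.all(self.progression_speed_values > 0), "speed factors must be > 0")
        _check(abs(self.progression_speed_probs.sum() - 1) < 1e-9,
               "speed mixture probs must sum to 1")
        _check(self.direct_right_colon_weight > 0, "right-colon weight must be > 0")
        _check(1 <= self.early_advanced_boundary <= 5, "early/advanced boundary in 1..5")
        _check(self.death_window_anchor in ("initiation", "diagnosis"), "bad death anchor")

    def risk_lognormal_mu(self) -> float:
        """mu of the lognormal risk multiplier so that its mean is exactly 1."""
        return -0.5 * self.risk_heterogeneity_sigma ** 2

    def direct_location_distribution(self) -> np.ndarray:
        w = self.location_distribution * np.where(
            RIGHT_COLON > 0, self.direct_right_colon_weight, 1.0
        )
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "adenoma_init_rate": {s: self.adenoma_init_rate[i].tolist() for i, s in enumerate(SEXES)},
            "risk_heterogeneity_sigma": float(self.risk_heterogeneity_sigma),
            "location_distribution": self.location_distribution.tolist(),
            "stage_progression_prob": self.stage_progression_prob.tolist(),
            "adenoma_to_preclinical_prob": self.adenoma_to_preclinical_prob.tolist(),
            "direct_path_rate": {s: self.direct_path_rate[i].tolist() for i, s in enumerate(SEXES)},
            "direct_right_colon_weight": float(self.direct_right_colon_weight),
            "preclinical_stage_progression_prob": self.preclinical_stage_progression_prob.tolist(),
            "symptomatic_detection_prob": self.symptomatic_detection_prob.tolist(),
            "stage_at_direct_onset": self.stage_at_direct_onset.tolist(),
            "survival_5yr": self.survival_5yr.tolist(),
            "crc_death_time_distribution": self.crc_death_time_distribution.tolist(),
            "progression_speed_values": self.progression_speed_values.tolist(),
            "progression_speed_probs": self.progression_speed_probs.tolist(),
            "early_advanced_boundary": int(self.early_advanced_boundary),
            "death_window_anchor": self.death_window_anchor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        d = dict(d)
        for key in ("adenoma_init_rate", "direct_path_rate"):
            d[key] = np.stack([np.asarray(d[key][s], float) for s in SEXES])
        return cls(**d)

    def scaled(self, adenoma_scale: float = 1.0, direct_scale: float | None = None) -> "NaturalHistoryParams":
        """Copy with the adenoma-initiation hazard (and optionally the
        direct-path hazard) multiplied by a scalar."""
        if direct_scale is None:
            direct_scale = adenoma_scale
        d = self.to_dict()
        out = NaturalHistoryParams.from_dict(d)
        out.adenoma_init_rate = out.adenoma_init_rate * adenoma_scale
        out.direct_path_rate = out.direct_path_rate * direct_scale
        return out


# ---------------------------------------------------------------------------
# Colonoscopy
# ---------------------------------------------------------------------------


@dataclass
class ColonoscopyParams:
    """Procedure performance: reach, detection, complications, adherence."""

    # probability of passing each insertion landmark, in scope order
    reach_prob_splenic: float
    reach_prob_hepatic: float
    reach_prob_cecum: float
    # per-lesion detection probability given the segment is visualized
    detection_sensitivity: np.ndarray  # adenoma stages 1..6, non-decreasing
    cancer_detection_sensitivity: float
    # per-procedure complication probabilities; multiplied when polypectomy done
    complication_prob: dict  # {perforation, bleeding, serosa_burn}
    complication_polypectomy_multiplier: float
    complication_fatality: dict  # {perforation, bleeding, serosa_burn}
    adherence: float = 1.0
    adherence_mode: str = "per_invitation"  # or "per_person"

    def __post_init__(self) -> None:
        self.detection_sensitivity = np.asarray(self.detection_sensitivity, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        for p in (self.reach_prob_splenic, self.reach_prob_hepatic, self.reach_prob_cecum,
                  self.cancer_detection_sensitivity, self.adherence):
            _check(0 <= p <= 1, "probability outside [0, 1]")
        _check(self.detection_sensitivity.shape == (6,), "detection sensitivity shape")
        _check(np.all((self.detection_sensitivity >= 0) & (self.detection_sensitivity <= 1)),
               "detection sensitivity outside [0, 1]")
        _check(np.all(np.diff(self.detection_sensitivity) >= -1e-12),
               "detection sensitivity must be non-decreasing in stage")
        for d in (self.complication_prob, self.complication_fatality):
            _check(set(d) == {"perforation", "bleeding", "serosa_burn"}, "complication keys")
            _check(all(0 <= v <= 1 for v in d.values()), "complication prob outside [0, 1]")
        _check(self.complication_polypectomy_multiplier >= 0, "polypectomy multiplier < 0")
        _check(self.adherence_mode in ("per_invitation", "per_person"), "bad adherence mode")

    def cecal_intubation_rate(self) -> float:
        return self.reach_prob_splenic * self.reach_prob_hepatic * self.reach_prob_cecum

    def to_dict(self) -> dict:
        return {
            "reach_prob_splenic": float(self.reach_prob_splenic),
            "reach_prob_hepatic": float(self.reach_prob_hepatic),
            "reach_prob_cecum": float(self.reach_prob_cecum),
            "detection_sensitivity": self.detection_sensitivity.tolist(),
            "cancer_detection_sensitivity": float(self.cancer_detection_sensitivity),
            "complication_prob": {k: float(v) for k, v in self.complication_prob.items()},
            "complication_polypectomy_multiplier": float(self.complication_polypectomy_multiplier),
            "complication_fatality": {k: float(v) for k, v in self.complication_fatality.items()},
            "adherence": float(self.adherence),
            "adherence_mode": self.adherence_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColonoscopyParams":
        return cls(**d)


@dataclass
class SurveillanceGuideline:
    """Interval (years) to the next surveillance exam, by findings category."""

    interval_low_risk: float = 5.0     # 1-2 early adenomas
    interval_high_risk: float = 3.0    # >=3 adenomas or any advanced adenoma
    stopping_age: float = 85.0

    def __post_init__(self) -> None:
        _check(self.interval_low_risk > 0 and self.interval_high_risk > 0,
               "surveillance intervals must be positive")
        _check(self.stopping_age <= 100, "stopping age must be <= 100")

    def to_dict(self) -> dict:
        return {
            "interval_low_risk": float(self.interval_low_risk),
            "interval_high_risk": float(self.interval_high_risk),
            "stopping_age": float(self.stopping_age),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurveillanceGuideline":
        return cls(**d)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

TREATMENT_PERIODS = ("initial12mo", "followup", "terminal12mo")


@dataclass
class CostParams:
    """Economic inputs (currency units; synthetic 2020-USD-scale defaults)."""

    colonoscopy_cost: float
    polypectomy_surcharge: float
    complication_cost: dict  # by complication type
    # per-quarter treatment cost, shape (4 stages, 3 periods) following TREATMENT_PERIODS
    treatment_cost: np.ndarray
    death_unrelated_terminal_cost: float
    discount_rate_annual: float = 0.03
    discount_anchor_age: float = 20.0
    treatment_horizon_q: int = 20  # treatment costs cease 5 years after diagnosis

    def __post_init__(self) -> None:
        self.treatment_cost = np.asarray(self.treatment_cost, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        _check(self.colonoscopy_cost >= 0 and self.polypectomy_surcharge >= 0, "negative cost")
        _check(all(v >= 0 for v in self.complication_cost.values()), "negative complication cost")
        _check(self.treatment_cost.shape == (4, 3), "treatment cost must be (4 stages, 3 periods)")
        _check(np.all(self.treatment_cost >= 0), "negative treatment cost")
        _check(self.death_unrelated_terminal_cost >= 0, "negative terminal cost")
        _check(0 <= self.discount_rate_annual < 1, "discount rate outside [0, 1)")
        _check(self.treatment_horizon_q == 20, "treatment horizon fixed at 20 quarters")

    def to_dict(self) -> dict:
        return {
            "colonoscopy_cost": float(self.colonoscopy_cost),
            "polypectomy_surcharge": float(self.polypectomy_surcharge),
            "complication_cost": {k: float(v) for k, v in self.complication_cost.items()},
            "treatment_cost": self.treatment_cost.tolist(),
            "death_unrelated_terminal_cost": float(self.death_unrelated_terminal_cost),
            "discount_rate_annual": float(self.discount_rate_annual),
            "discount_anchor_age": float(self.discount_anchor_age),
            "treatment_horizon_q": int(self.treatment_horizon_q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostParams":
        return cls(**d)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class ParamBundle:
    """Everything one simulation needs, serializable as one YAML document."""

    natural_history: NaturalHistoryParams
    colonoscopy: ColonoscopyParams
    costs: CostParams
    life_table: LifeTable
    guideline: SurveillanceGuideline = field(default_factory=SurveillanceGuideline)

    def to_dict(self) -> dict:
        return {
            "natural_history": self.natural_history.to_dict(),
            "colonoscopy": self.colonoscopy.to_dict(),
            "costs": self.costs.to_dict(),
            "life_table": self.life_table.to_dict(),
            "guideline": self.guideline.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamBundle":
        return cls(
            natural_history=NaturalHistoryParams.from_dict(d["natural_history"]),
            colonoscopy=ColonoscopyParams.from_dict(d["colonoscopy"]),
            costs=CostParams.from_dict(d["costs"]),
            life_table=LifeTable.from_dict(d["life_table"]),
            guideline=SurveillanceGuideline.from_dict(d["guideline"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ParamBundle":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
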