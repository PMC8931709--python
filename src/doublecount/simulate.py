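"""Synthetic double-observer aerial survey generator.

Generates a ground-truth flock list and the front/rear observer record
streams that a double-observer strip-transect survey would produce, with
configurable error processes:

* nondetection — per-observer Bernoulli detection, logit-linear and
  increasing in log10(flock size), optionally correlated between observers
  through a shared availability draw (Gaussian copula);
* counting error — a multiplicative lognormal count ratio whose mean is 1
  for small groups and declines with log10(size) (large flocks are counted
  at roughly 35-50% of truth by default), with spread growing in size;
* misidentification — replacement of the true taxon by a confusable
  same-family species, or by the family's generic code;
* timing — exponential inter-flock spacing plus per-observer recording lags
  (the rear observer lags the front by ~2 s by default).

The defaults emulate a winter nearshore waterbird survey: about 70% of
flocks are single birds, the size distribution is heavy-tailed into the
thousands, and gulls/terns are frequently recorded at the generic level.
A companion generator produces known-truth flock-counting quiz responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .quiz import CONFIDENCE_LEVELS, EXPERIENCE_LEVELS, QuizResponse
from .records import ObserverRecord, TaxonomyTable, write_records
from .summaries import ObserverSession

__all__ = [
    "FlockModel",
    "ObserverParams",
    "SimConfig",
    "SpeciesSpec",
    "SurveyData",
    "default_species_pool",
    "default_taxonomy",
    "draw_flocks",
    "observe_flock",
    "sim_config_from_yaml",
    "simulate_quiz",
    "simulate_survey",
]


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _phi(z: float) -> float:
    """Standard normal CDF via erf (fast scalar path)."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def default_taxonomy() -> TaxonomyTable:
    """A small nearshore-waterbird taxonomy for simulation and fixtures.

    Includes the species-like generic codes ``gull`` and ``tern`` (pooled
    under Laridae for family-level comparisons) and one plain generic code
    per family for generic-level identifications.
    """
    rows = [
        ("NOGA", "northern gannet", "Sulidae", "species"),
        ("BRPE", "brown pelican", "Pelecanidae", "species"),
        ("LAGU", "laughing gull", "Laridae", "species"),
        ("ROYT", "royal tern", "Laridae", "species"),
        ("gull", "gull (unidentified)", "Laridae", "generic"),
        ("tern", "tern (unidentified)", "Laridae", "generic"),
        ("larid", "gull/tern spp.", "Laridae", "generic"),
        ("WWSC", "white-winged scoter", "Anatidae", "species"),
        ("BLSC", "black scoter", "Anatidae", "species"),
        ("scoter", "scoter spp.", "Anatidae", "generic"),
        ("DCCO", "double-crested cormorant", "Phalacrocoracidae", "species"),
        ("cormorant", "cormorant spp.", "Phalacrocoracidae", "generic"),
        ("sulid", "gannet/booby spp.", "Sulidae", "generic"),
        ("pelican", "pelican spp.", "Pelecanidae", "generic"),
    ]
    return TaxonomyTable(rows)


@dataclass(frozen=True)
class SpeciesSpec:
    """One taxon in the simulated community."""

    taxon_code: str
    family_code: str
    relative_frequency: float
    confusable_codes: tuple[str, ...] = ()


def default_species_pool() -> tuple[SpeciesSpec, ...]:
    """Relative taxon frequencies echoing a Gulf winter community:
    gannets dominant, then gulls/terns, pelicans, and scattered others."""
    tax = default_taxonomy()

    def spec(code: str, freq: float) -> SpeciesSpec:
        fam = tax.family_of(code)
        confusable = tuple(c for c in tax.species_codes(fam) if c != code)
        return SpeciesSpec(code, fam, freq, confusable)

    return (
        spec("NOGA", 0.30),
        spec("gull", 0.20),
        spec("tern", 0.15),
        spec("BRPE", 0.10),
        spec("LAGU", 0.08),
        spec("ROYT", 0.05),
        spec("DCCO", 0.05),
        spec("WWSC", 0.04),
        spec("BLSC", 0.03),
    )


@dataclass(frozen=True)
class FlockModel:
    """Flock-size distribution: singleton spike plus a heavy lognormal tail.

    A flock is a single bird with probability ``p_singleton`` (default 0.70,
    the middle of the observed 66-77% singleton share); otherwise its size is
    a lognormal draw rounded and clamped to >= 2, which keeps the overall
    median at 1 while producing sizes into the thousands.
    """

    p_singleton: float = 0.70
    tail_log_mean: float = 1.6
    tail_log_sd: float = 1.4

    def __post_init__(self) -> None:
        if not 0 <= self.p_singleton <= 1:
            raise ValueError(f"p_singleton must be in [0, 1], got {self.p_singleton}")
        if self.tail_log_sd < 0:
            raise ValueError("tail_log_sd must be >= 0")


@dataclass(frozen=True)
class ObserverParams:
    """Per-observer error-process parameters.

    Detection is Bernoulli with logit p = detect_intercept +
    detect_slope_log10size * log10(size). The recorded count is
    max(1, round(size * R)) with R lognormal; E[R] interpolates from
    ``ratio_small`` (sizes <= small_size_max) down to ``ratio_at_1000`` at
    size 1000 on a log10 scale, and sd(R) from ``sd_small`` to ``sd_at_1000``.
    The true taxon is replaced by a confusable same-family species with
    probability ``misid_prob``, or by the family generic code with
    probability ``generic_id_prob`` (mutually exclusive draws). Recording
    time is the true time plus Normal(time_lag_mean_s, time_lag_sd_s).
    """

    observer_id: str = "obs"
    seat: str = "front"
    detect_intercept: float = 1.4
    detect_slope_log10size: float = 0.8
    ratio_small: float = 1.0
    ratio_at_1000: float = 0.45
    small_size_max: int = 5
    sd_small: float = 0.05
    sd_at_1000: float = 0.35
    misid_prob: float = 0.05
    generic_id_prob: float = 0.10
    time_lag_mean_s: float = 0.0
    time_lag_sd_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("misid_prob", "generic_id_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.misid_prob + self.generic_id_prob > 1:
            raise ValueError("misid_prob + generic_id_prob must be <= 1")
        if self.time_lag_sd_s < 0 or self.sd_small < 0 or self.sd_at_1000 < 0:
            raise ValueError("standard deviations must be >= 0")

    def detection_prob(self, size: int) -> float:
        return _expit(self.detect_intercept + self.detect_slope_log10size * math.log10(size))

    def _interp(self, size: int, at_small: float, at_1000: float) -> float:
        if size <= self.small_size_max:
            return at_small
        x0, x1 = math.log10(self.small_size_max), 3.0
        t = min(1.0, (math.log10(size) - x0) / (x1 - x0))
        return at_small + t * (at_1000 - at_small)

    def count_ratio_mean(self, size: int) -> float:
        return self._interp(size, self.ratio_small, self.ratio_at_1000)

    def count_ratio_sd(self, size: int) -> float:
        return self._interp(size, self.sd_small, self.sd_at_1000)

    @classmethod
    def perfect(cls, observer_id: str, seat: str) -> "ObserverParams":
        """Detection 1, exact counts, no misidentification, no timing noise."""
        return cls(
            observer_id=observer_id,
            seat=seat,
            detect_intercept=50.0,
            detect_slope_log10size=0.0,
            sd_small=0.0,
            sd_at_1000=0.0,
            ratio_at_1000=1.0,
            misid_prob=0.0,
            generic_id_prob=0.0,
            time_lag_mean_s=0.0,
            time_lag_sd_s=0.0,
        )

    @classmethod
    def constant_detection(cls, p: float, observer_id: str, seat: str) -> "ObserverParams":
        """Size-independent detection p; all other error processes off."""
        return replace(
            cls.perfect(observer_id, seat),
            detect_intercept=_logit(p) if p < 1 else 50.0,
            detect_slope_log10size=0.0,
        )


def _default_front() -> ObserverParams:
    return ObserverParams(observer_id="front1", seat="front")


def _default_rear() -> ObserverParams:
    # rear visibility is poorer and recording lags the front by ~2 s
    return ObserverParams(
        observer_id="rear1", seat="rear", detect_intercept=1.0, time_lag_mean_s=2.0
    )


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration; the defaults are the study conditions."""

    seed: int = 0
    n_flocks: int = 1000
    survey_event: str = "sim"
    unit_id: str = "U1"
    transect_id: str = "T1"
    spacing_mean_s: float = 30.0
    spacing_dist: str = "exponential"
    detection_correlation: float = 0.0
    flock: FlockModel = field(default_factory=FlockModel)
    front: ObserverParams = field(default_factory=_default_front)
    rear: ObserverParams = field(default_factory=_default_rear)
    species_pool: tuple[SpeciesSpec, ...] = field(default_factory=default_species_pool)

    def __post_init__(self) -> None:
        if self.n_flocks < 1:
            raise ValueError("n_flocks must be >= 1")
        if not 0 <= self.detection_correlation <= 1:
            raise ValueError("detection_correlation must be in [0, 1]")
        if self.spacing_dist not in ("exponential", "fixed"):
            raise ValueError(f"spacing_dist must be exponential/fixed, got {self.spacing_dist!r}")
        total = sum(s.relative_frequency for s in self.species_pool)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"species relative frequencies must sum to 1, got {total}")

    @classmethod
    def zero_error(cls, n_flocks: int = 100, seed: int = 0, **kwargs) -> "SimConfig":
        """Both observers perfect: every flock yields a SpeciesCountMatch.

        Uses fixed inter-flock spacing so every flock is temporally isolated
        within the matching window.
        """
        kwargs.setdefault("spacing_dist", "fixed")
        return cls(
            seed=seed,
            n_flocks=n_flocks,
            front=ObserverParams.perfect("front1", "front"),
            rear=ObserverParams.perfect("rear1", "rear"),
            **kwargs,
        )

    @classmethod
    def independent_detection(
        cls, p_front: float, p_rear: float, n_flocks: int, seed: int = 0, **kwargs
    ) -> "SimConfig":
        """Constant independent detection probabilities; no other errors.

        Defaults to fixed inter-flock spacing: the analytic expectations for
        this design (no-match share 2(1-p)/(2-p), naive detection = p,
        unbiased Chapman N_hat) are derived under temporally isolated flocks,
        where no record can pair across flocks. Pass
        ``spacing_dist="exponential"`` to stress the matching window instead.
        """
        kwargs.setdefault("spacing_dist", "fixed")
        return cls(
            seed=seed,
            n_flocks=n_flocks,
            front=ObserverParams.constant_detection(p_front, "front1", "front"),
            rear=ObserverParams.constant_detection(p_rear, "rear1", "rear"),
            **kwargs,
        )


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return {
        name: np.random.default_rng(seq)
        for name, seq in zip(("flocks", "shared", "front", "rear"), children)
    }


def draw_flocks(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the ground-truth flock list (TruthTable).

    Columns: flock_id, true_taxon, true_size, true_time_s, side; times are
    non-decreasing, sizes >= 1.
    """
    rng = rng if rng is not None else _child_rngs(cfg.seed)["flocks"]
    n = cfg.n_flocks
    singleton = rng.random(n) < cfg.flock.p_singleton
    tail = np.maximum(
        2, np.rint(rng.lognormal(cfg.flock.tail_log_mean, cfg.flock.tail_log_sd, n))
    ).astype(int)
    sizes = np.where(singleton, 1, tail)
    codes = [s.taxon_code for s in cfg.species_pool]
    freqs = [s.relative_frequency for s in cfg.species_pool]
    taxa = rng.choice(codes, size=n, p=freqs)
    if cfg.spacing_dist == "fixed":
        times = cfg.spacing_mean_s * np.arange(1, n + 1, dtype=float)
    else:
        times = np.cumsum(rng.exponential(cfg.spacing_mean_s, n))
    sides = rng.choice(["left", "right"], size=n)
    return pd.DataFrame(
        {
            "flock_id": np.arange(n),
            "true_taxon": taxa,
            "true_size": sizes,
            "true_time_s": times,
            "side": sides,
        }
    )


def observe_flock(
    flock: Mapping,
    params: ObserverParams,
    rng: np.random.Generator,
    cfg: SimConfig,
    tax: TaxonomyTable,
    z_shared: float | None = None,
) -> ObserverRecord | None:
    """Simulate one observer's record of one true flock (or a miss).

    ``flock`` is a row of the truth table. With detection_correlation c > 0,
    ``z_shared`` is the flock's shared availability draw and the observer's
    detection uses z = sqrt(c) z_shared + sqrt(1-c) z_own (Gaussian copula:
    marginal detection probability is preserved, joint detection is
    positively correlated).
    """
    size = int(flock["true_size"])
    p = params.detection_prob(size)
    c = cfg.detection_correlation
    z_own = rng.standard_normal()
    if c > 0 and z_shared is not None:
        z = math.sqrt(c) * z_shared + math.sqrt(1 - c) * z_own
    else:
        z = z_own
    if _phi(z) >= p:
        return None

    m, sd = params.count_ratio_mean(size), params.count_ratio_sd(size)
    if sd > 0:
        sigma2 = math.log(1 + (sd / m) ** 2)
        mu = math.log(m) - sigma2 / 2
        ratio = math.exp(mu + math.sqrt(sigma2) * rng.standard_normal())
    else:
        ratio = m
    recorded = max(1, round(size * ratio))

    taxon = str(flock["true_taxon"])
    u = rng.random()
    if u < params.misid_prob:
        spec = next(s for s in cfg.species_pool if s.taxon_code == taxon)
        if spec.confusable_codes:
            taxon = spec.confusable_codes[rng.integers(len(spec.confusable_codes))]
    elif u < params.misid_prob + params.generic_id_prob:
        generic = tax.generic_code(tax.family_of(taxon))
        if generic is not None:
            taxon = generic

    if params.time_lag_sd_s > 0 or params.time_lag_mean_s != 0:
        t = flock["true_time_s"] + params.time_lag_mean_s + params.time_lag_sd_s * rng.standard_normal()
    else:
        t = flock["true_time_s"]
    return ObserverRecord(
        record_id=f"{params.seat[0].upper()}{int(flock['flock_id']):06d}",
        survey_event=cfg.survey_event,
        unit_id=cfg.unit_id,
        transect_id=cfg.transect_id,
        side=str(flock["side"]),
        seat=params.seat,
        observer_id=params.observer_id,
        time_s=max(0.0, float(t)),
        taxon_code=taxon,
        count=recorded,
    )


@dataclass
class SurveyData:
    """A simulated survey: two record streams plus the generating truth."""

    front: list[ObserverRecord]
    rear: list[ObserverRecord]
    truth: pd.DataFrame
    taxonomy: TaxonomyTable
    sessions: list[ObserverSession]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "front": out / "front.csv",
            "rear": out / "rear.csv",
            "truth": out / "truth.csv",
            "taxonomy": out / "taxonomy.csv",
        }
        write_records(self.front, paths["front"])
        write_records(self.rear, paths["rear"])
        self.truth.to_csv(paths["truth"], index=False)
        self.taxonomy.to_csv(paths["taxonomy"])
        return paths


def simulate_survey(cfg: SimConfig, tax: TaxonomyTable | None = None) -> SurveyData:
    """Generate truth and both observer streams for one survey.

    Identical (seed, config) inputs yield identical output, byte-for-byte
    when written to CSV.
    """
    tax = tax or default_taxonomy()
    rngs = _child_rngs(cfg.seed)
    truth = draw_flocks(cfg, rngs["flocks"])
    z_shared = rngs["shared"].standard_normal(cfg.n_flocks)
    front: list[ObserverRecord] = []
    rear: list[ObserverRecord] = []
    rows = truth.to_dict("records")
    for i, row in enumerate(rows):
        rec = observe_flock(row, cfg.front, rngs["front"], cfg, tax, z_shared=z_shared[i])
        if rec is not None:
            front.append(rec)
        rec = observe_flock(row, cfg.rear, rngs["rear"], cfg, tax, z_shared=z_shared[i])
        if rec is not None:
            rear.append(rec)
    sessions = [
        ObserverSession(cfg.survey_event, cfg.front.observer_id, cfg.rear.observer_id, side, "front")
        for side in ("left", "right")
    ] + [
        ObserverSession(cfg.survey_event, cfg.rear.observer_id, cfg.front.observer_id, side, "rear")
        for side in ("left", "right")
    ]
    return SurveyData(front=front, rear=rear, truth=truth, taxonomy=tax, sessions=sessions)


# ---------------------------------------------------------------------------
# quiz generator

DEFAULT_QUIZ_IMAGE_SIZES = (
    4, 6, 9, 12, 15, 20, 25, 30, 40, 50, 60, 75, 90, 110,
    150, 200, 250, 300, 400, 500, 750, 1000,
)  # 22 known-truth images spanning the observed flock-size range


def simulate_quiz(
    seed: int = 0,
    image_sizes: Sequence[int] = DEFAULT_QUIZ_IMAGE_SIZES,
    n_per_experience: Mapping[str, int] | None = None,
    error_scale_by_experience: Mapping[str, float] | None = None,
    counter: ObserverParams | None = None,
) -> list[QuizResponse]:
    """Generate known-truth quiz responses with the survey counting model.

    Respondents apply the same multiplicative counting-error model as
    in-flight observers; by default experience has no effect on error
    (``error_scale_by_experience`` multiplies the ratio sd per group to
    inject one). 78 respondents across four experience levels by default.
    """
    rng = np.random.default_rng(seed)
    counter = counter or ObserverParams(observer_id="quiz", sd_small=0.12)
    n_per = dict(n_per_experience or {"Expert": 20, "Intermediate": 20, "Novice": 19, "NoExperience": 19})
    scales = dict(error_scale_by_experience or {})
    responses: list[QuizResponse] = []
    r_idx = 0
    for exp in EXPERIENCE_LEVELS:
        for _ in range(n_per.get(exp, 0)):
            rid = f"R{r_idx:03d}"
            r_idx += 1
            confidence = CONFIDENCE_LEVELS[rng.integers(len(CONFIDENCE_LEVELS))]
            scale = scales.get(exp, 1.0)
            for img, true in enumerate(image_sizes):
                m = counter.count_ratio_mean(true)
                sd = max(1e-9, counter.count_ratio_sd(true) * scale)
                sigma2 = math.log(1 + (sd / m) ** 2)
                mu = math.log(m) - sigma2 / 2
                ratio = math.exp(mu + math.sqrt(sigma2) * rng.standard_normal())
                responses.append(
                    QuizResponse(
                        respondent_id=rid,
                        experience=exp,
                        confidence=confidence,
                        image_id=f"img{img:02d}",
                        true_count=int(true),
                        response=max(0, round(true * ratio)),
                    )
                )
    return responses


# ---------------------------------------------------------------------------
# YAML config

def sim_config_from_yaml(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file.

    Top-level scalar fields map directly; ``flock``, ``front`` and ``rear``
    are nested mappings; ``species_pool`` is a list of mappings with
    taxon_code, family_code, relative_frequency and optional
    confusable_codes. Omitted values keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "seed", "n_flocks", "survey_event", "unit_id", "transect_id",
        "spacing_mean_s", "spacing_dist", "detection_correlation",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "flock" in raw:
        kwargs["flock"] = FlockModel(**raw["flock"])
    for seat in ("front", "rear"):
        if seat in raw:
            base = _default_front() if seat == "front" else _default_rear()
            kwargs[seat] = replace(base, **raw[seat])
    if "species_pool" in raw:
        kwargs["species_pool"] = tuple(
            SpeciesSpec(
                taxon_code=s["taxon_code"],
                family_code=s["family_code"],
                relative_frequency=s["relative_frequency"],
                confusable_codes=tuple(s.get("confusable_codes", ())),
            )
            for s in raw["species_pool"]
        )
    return SimConfig(**kwargs)
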