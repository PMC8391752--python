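"""Synthetic longitudinal checkup cohort generator.

Emulates the statistical structure of a proprietary health-screening
dataset so the whole prediction pipeline can be exercised with known
ground truth: irregular inter-visit intervals, single- and multi-visit
subjects, gender-dependent NFLD:FLD class-size ratios, heavy per-feature
missingness (including near-completely-missing features), a small set of
truly informative adiposity-related features among many noise features,
and calibrated label persistence across consecutive visits.

Label model
-----------
Each subject carries a latent "adiposity" trajectory a(t) following a
Gaussian random walk across visits (step variance proportional to the
elapsed time).  Informative features load on a(t) plus independent noise.
The per-visit FLD propensity is a logistic link

    p_t = sigmoid(b0_g + sum_j beta_j x_jt)

with a gender intercept b0_g solved numerically so that the marginal
prevalence matches the requested NFLD/FLD class-size ratio.  Consecutive
labels are tied together by a persistence-calibrated mixture: writing
c_t for the probability that a fresh draw from p_t agrees with the
previous label, the generator copies the previous label with probability
(rho - c_t)/(1 - c_t) when c_t < rho, and when c_t >= rho it flips an
agreeing fresh draw with probability 1 - rho/c_t.  Either way the
per-pair agreement probability is exactly rho = ``label_persistence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, FeatureDef, FeatureSchema, SubjectHistory, Visit

# stand-in names for the informative adiposity-related measurements
_INFORMATIVE_NAMES = ["bmi", "body_fat", "waist", "triglyceride", "fasting_glucose"]


@dataclass(frozen=True)
class IntDistSpec:
    """Bounded integer distribution: ``min + Binomial(max - min, p)`` with
    p chosen so the mean matches ``mean``."""

    min: int
    max: int
    mean: float

    def __post_init__(self) -> None:
        if self.min < 0 or self.max < self.min:
            raise ValueError(f"invalid integer distribution bounds [{self.min}, {self.max}]")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"mean {self.mean} outside [{self.min}, {self.max}]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        span = self.max - self.min
        if span == 0:
            return np.full(size, self.min, dtype=int)
        p = (self.mean - self.min) / span
        return self.min + rng.binomial(span, p, size=size)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions: 2,000 subjects, five
    informative features among 25 noise features, label persistence 0.8,
    and gender class-size ratios matching the screening population the
    generator emulates (NFLD/FLD 0.66 for males, 2.02 for females).
    """

    n_subjects: int = 2000
    visits_per_subject: IntDistSpec = IntDistSpec(1, 8, 3.5)
    interval_months: IntDistSpec = IntDistSpec(3, 24, 12)
    gender_mix: float = 0.5  # fraction male
    n_informative: int = 5
    n_noise_numeric: int = 15
    n_noise_categorical: int = 10
    categorical_levels: int = 4
    effect_sizes: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6)
    label_persistence: float = 0.8
    missing_rates: Union[float, Mapping[str, float], None] = None
    target_class_ratio: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.66, "female": 2.02}
    )
    birth_year_range: tuple[int, int] = (1945, 1990)
    first_visit_year_range: tuple[int, int] = (2009, 2012)
    latent_autocorr_year: float = 0.98  # 1-year autocorrelation of the latent adiposity
    feature_noise_sd: float = 0.5
    # optional age-dependent attenuation of the feature->label link
    attenuation_age: Optional[int] = None
    attenuation_factor: float = 1.0
    # optional sign flip of the link before a calendar year (distribution shift)
    effect_flip_before_year: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for frac, name in [(self.gender_mix, "gender_mix"), (self.label_persistence, "label_persistence")]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.interval_months.min < 1:
            raise ValueError("interval_months support must be positive integers")
        if self.visits_per_subject.min < 1:
            raise ValueError("every subject has at least one visit")
        if self.categorical_levels < 2:
            raise ValueError("categorical_levels must be >= 2")
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError(
                f"effect_sizes has {len(self.effect_sizes)} entries for "
                f"{self.n_informative} informative features"
            )
        for g in ("male", "female"):
            if self.target_class_ratio[g] < 0:
                raise ValueError("target class ratios must be non-negative")


def informative_names(n: int) -> list[str]:
    names = list(_INFORMATIVE_NAMES[:n])
    names += [f"informative_{i}" for i in range(len(names) + 1, n + 1)]
    return names


def build_schema(params: GeneratorParams) -> FeatureSchema:
    feats: list[FeatureDef] = []
    for name in informative_names(params.n_informative):
        feats.append(FeatureDef(name, "numeric", expert=True))
    for i in range(1, params.n_noise_numeric + 1):
        feats.append(FeatureDef(f"noise_num_{i}", "numeric"))
    for i in range(1, params.n_noise_categorical + 1):
        feats.append(FeatureDef(f"noise_cat_{i}", "categorical", (0, params.categorical_levels - 1)))
    return FeatureSchema(tuple(feats))


def default_missing_rates(params: GeneratorParams) -> dict[str, float]:
    """Default missingness profile: light missingness on informative
    features, moderate on noise, and the last two numeric noise features
    nearly completely missing (>= 90%), mirroring real screening data."""
    rates: dict[str, float] = {}
    for name in informative_names(params.n_informative):
        rates[name] = 0.05
    for i in range(1, params.n_noise_numeric + 1):
        rates[f"noise_num_{i}"] = 0.10
    for i in range(1, params.n_noise_categorical + 1):
        rates[f"noise_cat_{i}"] = 0.10
    for i in range(max(1, params.n_noise_numeric - 1), params.n_noise_numeric + 1):
        rates[f"noise_num_{i}"] = 0.95
    return rates


def _resolve_missing_rates(params: GeneratorParams, schema: FeatureSchema) -> dict[str, float]:
    if params.missing_rates is None:
        rates = default_missing_rates(params)
    elif isinstance(params.missing_rates, (int, float)):
        rates = {name: float(params.missing_rates) for name in schema.names}
    else:
        rates = {name: 0.0 for name in schema.names}
        rates.update({k: float(v) for k, v in params.missing_rates.items()})
    for name, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missing rate for {name!r} outside [0, 1]: {r}")
    return rates


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Solve mean(sigmoid(b0 + eta)) = prevalence for b0."""
    if eta.size == 0:
        return 0.0
    if prevalence <= 0.0:
        return -30.0
    if prevalence >= 1.0:
        return 30.0

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - prevalence

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Generate a synthetic cohort. Identical params (including seed)
    reproduce the identical cohort."""
    schema = build_schema(params)
    rates = _resolve_missing_rates(params, schema)
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    inf_names = informative_names(params.n_informative)
    betas = np.asarray(params.effect_sizes, dtype=float)

    n_visits = params.visits_per_subject.sample(rng, n)
    max_v = int(n_visits.max()) if n else 1
    male = rng.random(n) < params.gender_mix
    birth_year = rng.integers(params.birth_year_range[0], params.birth_year_range[1] + 1, size=n)

    y0, y1 = params.first_visit_year_range
    first_month = rng.integers(y0 * 12, (y1 + 1) * 12, size=n)
    intervals = params.interval_months.sample(rng, (n, max(max_v - 1, 1)) if n else 0)
    intervals = intervals.reshape(n, -1) if n else np.zeros((0, 1), dtype=int)
    months = np.concatenate([first_month[:, None], first_month[:, None] + np.cumsum(intervals, axis=1)], axis=1)
    months = months[:, :max_v]
    valid = np.arange(max_v)[None, :] < n_visits[:, None]  # (n, max_v)

    # latent adiposity: stationary mean-reverting (AR(1)/OU) trajectory with
    # a slow, time-scaled autocorrelation — adiposity drifts, it does not wander off
    lat = np.zeros((n, max_v))
    if n:
        lat[:, 0] = rng.standard_normal(n)
        for t in range(1, max_v):
            dt = (months[:, t] - months[:, t - 1]) / 12.0
            phi = params.latent_autocorr_year**dt
            lat[:, t] = phi * lat[:, t - 1] + np.sqrt(1.0 - phi**2) * rng.standard_normal(n)

    # informative features load on the latent trajectory
    x_inf = lat[:, :, None] + params.feature_noise_sd * rng.standard_normal((n, max_v, len(inf_names)))

    eta = np.tensordot(x_inf, betas, axes=([2], [0]))  # (n, max_v)
    visit_year = months // 12
    mult = np.ones((n, max_v))
    if params.attenuation_age is not None:
        age = visit_year - birth_year[:, None]
        mult = np.where(age >= params.attenuation_age, params.attenuation_factor, mult)
    if params.effect_flip_before_year is not None:
        mult = np.where(visit_year < params.effect_flip_before_year, -mult, mult)
    eta = eta * mult

    # gender intercepts: start from the fresh-draw solution, then calibrate
    # against the realized chain prevalence (the persistence mixture's
    # forced flips are slightly asymmetric between the classes)
    b0 = np.zeros(n)
    target_prev = {}
    for g, is_g in (("male", male), ("female", ~male)):
        ratio = float(params.target_class_ratio[g])
        target_prev[g] = 1.0 / (1.0 + ratio)  # ratio is NFLD/FLD, FLD is positive
        sel = is_g[:, None] & valid
        b0[is_g] = _solve_intercept(eta[sel], target_prev[g])

    rho = params.label_persistence

    def sample_chain(b0_vec: np.ndarray, mix: float, chain_rng: np.random.Generator) -> np.ndarray:
        """Fresh logistic draws per visit, blended with an explicit
        persistence term: with probability |mix| the previous label is
        copied (mix > 0) or inverted (mix < 0), otherwise a fresh draw."""
        p = expit(b0_vec[:, None] + eta)  # (n, max_v) fresh-draw propensities
        labels = np.zeros((n, max_v), dtype=int)
        labels[:, 0] = chain_rng.random(n) < p[:, 0]
        for t in range(1, max_v):
            prev = labels[:, t - 1]
            fresh = (chain_rng.random(n) < p[:, t]).astype(int)
            forced = chain_rng.random(n) < abs(mix)
            if mix >= 0:
                labels[:, t] = np.where(forced, prev, fresh)
            else:
                labels[:, t] = np.where(forced, 1 - prev, fresh)
        return labels

    labels = np.zeros((n, max_v), dtype=int)
    if n:
        def _logit(q: float) -> float:
            q = min(max(q, 1e-6), 1 - 1e-6)
            return float(np.log(q / (1.0 - q)))

        def _agreement(lab: np.ndarray) -> float:
            pair_mask = valid[:, 1:] & valid[:, :-1]
            if pair_mask.sum() == 0:
                return rho
            return float((lab[:, 1:] == lab[:, :-1])[pair_mask].mean())

        # fixed-point calibration with common random numbers: the chain is
        # redrawn with the same underlying uniforms while the gender
        # intercepts (prevalence) and the persistence mix (consecutive-label
        # agreement) are adjusted, so the realized statistics converge to
        # the targets for this very cohort, not just in expectation
        mix = 0.0
        n_cal = 12
        for it in range(n_cal + 1):
            labels = sample_chain(b0, mix, np.random.default_rng([params.seed, 7]))
            if it == n_cal:
                break
            for g, is_g in (("male", male), ("female", ~male)):
                sel = is_g[:, None] & valid
                if sel.sum() == 0:
                    continue
                realized = float(labels[sel].mean())
                b0[is_g] += 1.5 * (_logit(target_prev[g]) - _logit(realized))
            # invert the mixing identity to re-solve for mix:
            # A = mix + (1 - mix) * A0 for mix >= 0, A = (1 - |mix|) * A0 otherwise
            A = _agreement(labels)
            if mix >= 0:
                a0 = (A - mix) / (1.0 - mix) if mix < 1 else A
            else:
                a0 = A / (1.0 - abs(mix)) if abs(mix) < 1 else A
            a0 = min(max(a0, 1e-6), 1 - 1e-6)
            if rho >= a0:
                mix = (rho - a0) / (1.0 - a0)
            else:
                mix = -(1.0 - rho / a0)
            mix = float(np.clip(mix, -1.0, 1.0))

    # noise features and missingness masks
    x_noise = rng.standard_normal((n, max_v, params.n_noise_numeric))
    x_cat = rng.integers(0, params.categorical_levels, size=(n, max_v, params.n_noise_categorical))
    all_names = schema.names
    miss = rng.random((n, max_v, len(all_names))) < np.array([rates[nm] for nm in all_names])[None, None, :]

    col_of = {nm: j for j, nm in enumerate(all_names)}
    noise_num_names = [f"noise_num_{i}" for i in range(1, params.n_noise_numeric + 1)]
    noise_cat_names = [f"noise_cat_{i}" for i in range(1, params.n_noise_categorical + 1)]

    subjects: list[SubjectHistory] = []
    for i in range(n):
        sid = f"S{i:06d}"
        visits: list[Visit] = []
        for t in range(int(n_visits[i])):
            numeric: dict[str, float] = {}
            categorical: dict[str, int] = {}
            for j, nm in enumerate(inf_names):
                if not miss[i, t, col_of[nm]]:
                    numeric[nm] = float(x_inf[i, t, j])
            for j, nm in enumerate(noise_num_names):
                if not miss[i, t, col_of[nm]]:
                    numeric[nm] = float(x_noise[i, t, j])
            for j, nm in enumerate(noise_cat_names):
                if not miss[i, t, col_of[nm]]:
                    categorical[nm] = int(x_cat[i, t, j])
            visits.append(
                Visit(
                    subject_id=sid,
                    year=int(months[i, t]) // 12,
                    month=int(months[i, t]) % 12 + 1,
                    numeric=numeric,
                    categorical=categorical,
                    fld_label=int(labels[i, t]),
                )
            )
        subjects.append(
            SubjectHistory(
                subject_id=sid,
                gender="male" if male[i] else "female",
                birth_year=int(birth_year[i]),
                visits=visits,
            )
        )
    return Cohort(schema=schema, subjects=subjects, ground_truth=frozenset(inf_names))


__all__ = [
    "IntDistSpec",
    "GeneratorParams",
    "generate_cohort",
    "build_schema",
    "default_missing_rates",
    "informative_names",
]
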