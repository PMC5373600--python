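"""Synthetic breast-lesion cohorts for exercising the DWI pipeline.

Two generators are provided:

* :func:`generate_cohort` — a stochastic cohort sampler.  Lesion class
  (benign/malignant), DWI visibility, lesion type, morphological
  descriptors, ADC, size and BI-RADS category are drawn from class-
  conditional distributions; :func:`default_config` calibrates every
  distribution to the class-conditional frequencies of the reference
  study setting (144 lesions, 112 malignant; benign ADC 1.14 +/- 0.23,
  malignant 0.88 +/- 0.19, each truncated to the observed range;
  DCE operating point sensitivity 99.11% / specificity 34.38%).
  Descriptors are sampled independently given (class, lesion type) — only
  marginal frequencies are emulated, not descriptor correlations.

* :func:`engineered_study_cohort` — a deterministic synthetic stand-in for
  the study's per-lesion dataset, constructed so that its *joint* counts of
  (class, qualitative score, ADC dichotomy, BI-RADS category) reproduce the
  published marginal tables exactly: the n=144 -> n=141 visibility
  accounting, the score x ADC and BI-RADS x ADC cross-tables, and the
  confusion matrices of all five diagnostic readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import stats

from .lesion_schema import (
    Distribution,
    InternalPattern,
    LesionRecord,
    LesionType,
    Margin,
    Pathology,
    Shape,
)

__all__ = ["ClassParams", "CohortConfig", "default_config", "generate_cohort",
           "engineered_study_cohort", "truncated_normal_mean"]

_PROB_TOL = 1e-9


def _check_probs(name: str, probs: Mapping) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional sampling distributions for one pathology class."""

    p_invisible: float
    p_mass: float  # P(mass | visible)
    shape_probs: Mapping[Shape, float]
    margin_probs: Mapping[Margin, float]
    distribution_probs: Mapping[Distribution, float]
    pattern_probs: Mapping[InternalPattern, float]
    adc_mean: float
    adc_sd: float
    adc_range: tuple[float, float]
    size_median_cm: float
    size_sigma_log: float
    size_range_cm: tuple[float, float]
    birads_probs: Mapping[int, float]

    def __post_init__(self) -> None:
        if not 0 <= self.p_invisible <= 1 or not 0 <= self.p_mass <= 1:
            raise ValueError("p_invisible and p_mass must be in [0, 1]")
        for name, probs in (("shape", self.shape_probs),
                            ("margin", self.margin_probs),
                            ("distribution", self.distribution_probs),
                            ("internal_pattern", self.pattern_probs),
                            ("birads", self.birads_probs)):
            _check_probs(name, probs)
        if not self.adc_sd > 0:
            raise ValueError("adc_sd must be > 0")
        if not self.adc_range[0] < self.adc_range[1]:
            raise ValueError("adc truncation range is empty")
        if not self.size_range_cm[0] < self.size_range_cm[1]:
            raise ValueError("size truncation range is empty")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort (see :func:`default_config`)."""

    n_lesions: int
    prevalence_malignant: float
    benign: ClassParams
    malignant: ClassParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError(f"n_lesions must be >= 1, got {self.n_lesions}")
        if not 0 <= self.prevalence_malignant <= 1:
            raise ValueError("prevalence_malignant must be in [0, 1]")


def default_config(n_lesions: int = 144, seed: int = 0) -> CohortConfig:
    """The reference study conditions, field by field.

    * prevalence 112/144 malignant; 3 of the 32 benign lesions invisible on
      DWI, no invisible malignant lesion;
    * lesion type given visible: benign 22 mass / 7 non-mass, malignant
      97 mass / 15 non-mass;
    * descriptor frequencies from the class-conditional counts of the
      descriptor tables — e.g. benign mass shape oval:round:irregular
      = 12:1:10, malignant margin circumscribed:irregular:spiculated
      = 6:73:17, internal pattern (both types) benign 21:8:0 and malignant
      18:69:25 over homogeneous:heterogeneous:rim;
    * per-lesion ADC ~ Gaussian truncated to the class's observed range:
      benign mean 1.14, SD 0.23 on [0.66, 1.58]; malignant mean 0.88,
      SD 0.19 on [0.42, 1.36] (1e-3 mm^2/s);
    * size ~ log-normal matched to the class median and mean (benign median
      0.75 cm, malignant 2.0 cm), truncated to the observed range;
    * BI-RADS per class: benign 3:4:5 = 11:21:0 over 32, malignant
      1:7:104 over 112 — giving P(BI-RADS >= 4) = 0.6562 benign and
      0.9911 malignant, the DCE operating point, with category totals
      12 / 28 / 104 in expectation at n = 144.
    """
    benign = ClassParams(
        p_invisible=3 / 32,
        p_mass=22 / 29,
        shape_probs={Shape.OVAL: 12 / 23, Shape.ROUND: 1 / 23,
                     Shape.IRREGULAR: 10 / 23},
        margin_probs={Margin.CIRCUMSCRIBED: 9 / 23, Margin.IRREGULAR: 14 / 23,
                      Margin.SPICULATED: 0.0},
        distribution_probs={Distribution.FOCAL: 1.0, Distribution.LINEAR: 0.0,
                            Distribution.SEGMENTAL: 0.0},
        pattern_probs={InternalPattern.HOMOGENEOUS: 21 / 29,
                       InternalPattern.HETEROGENEOUS: 8 / 29,
                       InternalPattern.RIM: 0.0},
        adc_mean=1.14, adc_sd=0.23, adc_range=(0.66, 1.58),
        size_median_cm=0.75,
        size_sigma_log=float(np.sqrt(2 * np.log(1.03 / 0.75))),
        size_range_cm=(0.3, 6.8),
        birads_probs={1: 0.0, 2: 0.0, 3: 11 / 32, 4: 21 / 32, 5: 0.0},
    )
    malignant = ClassParams(
        p_invisible=0.0,
        p_mass=97 / 112,
        shape_probs={Shape.OVAL: 11 / 96, Shape.ROUND: 4 / 96,
                     Shape.IRREGULAR: 81 / 96},
        margin_probs={Margin.CIRCUMSCRIBED: 6 / 96, Margin.IRREGULAR: 73 / 96,
                      Margin.SPICULATED: 17 / 96},
        distribution_probs={Distribution.FOCAL: 3 / 15, Distribution.LINEAR: 2 / 15,
                            Distribution.SEGMENTAL: 10 / 15},
        pattern_probs={InternalPattern.HOMOGENEOUS: 18 / 112,
                       InternalPattern.HETEROGENEOUS: 69 / 112,
                       InternalPattern.RIM: 25 / 112},
        adc_mean=0.88, adc_sd=0.19, adc_range=(0.42, 1.36),
        size_median_cm=2.0,
        size_sigma_log=float(np.sqrt(2 * np.log(2.42 / 2.0))),
        size_range_cm=(0.5, 10.2),
        birads_probs={1: 0.0, 2: 0.0, 3: 1 / 112, 4: 7 / 112, 5: 104 / 112},
    )
    return CohortConfig(n_lesions=n_lesions,
                        prevalence_malignant=float(Fraction(112, 144)),
                        benign=benign, malignant=malignant, seed=seed)


def truncated_normal_mean(mean: float, sd: float,
                          lo: float, hi: float) -> float:
    """Mean of a Gaussian truncated to [lo, hi] (oracle for recovery tests)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def _draw_categorical(u: np.ndarray, probs: Mapping) -> list:
    """Map uniforms to category values via the cumulative distribution."""
    values = list(probs.keys())
    cum = np.cumsum([probs[v] for v in values])
    cum[-1] = 1.0  # guard rounding
    idx = np.searchsorted(cum, u, side="right")
    return [values[min(i, len(values) - 1)] for i in idx]


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _trunc_lognorm_ppf(u: np.ndarray, median: float, sigma: float,
                       lo: float, hi: float) -> np.ndarray:
    # inverse-CDF sampling restricted to [lo, hi]
    dist = stats.lognorm(s=sigma, scale=median)
    flo, fhi = dist.cdf(lo), dist.cdf(hi)
    return dist.ppf(flo + u * (fhi - flo))


def generate_cohort(config: CohortConfig) -> list[LesionRecord]:
    """Sample a cohort of validated :class:`LesionRecord`\\ s.

    Deterministic given ``(config, config.seed)``: all random draws come
    from one ``numpy`` generator consumed in a fixed field order, and
    continuous quantities are produced by inverse-CDF transforms of uniform
    draws (exact truncated sampling, no rejection loops).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lesions
    # fixed draw order: class, visibility, type, shape, margin,
    # distribution, pattern, adc, size, birads
    u = {name: rng.random(n) for name in
         ("class", "visible", "type", "shape", "margin", "distribution",
          "pattern", "adc", "size", "birads")}
    is_mal = u["class"] < config.prevalence_malignant

    # vectorized per-class transforms of the uniform draws
    cols: dict[str, list] = {name: [None] * n for name in
                             ("shape", "margin", "distribution", "pattern")}
    adc = np.empty(n)
    size = np.empty(n)
    birads = [0] * n
    visible = np.empty(n, dtype=bool)
    is_mass = np.empty(n, dtype=bool)
    for mal, params in ((False, config.benign), (True, config.malignant)):
        idx = np.flatnonzero(is_mal == mal)
        if idx.size == 0:
            continue
        visible[idx] = u["visible"][idx] >= params.p_invisible
        is_mass[idx] = u["type"][idx] < params.p_mass
        for i, v in zip(idx, _draw_categorical(u["shape"][idx],
                                               params.shape_probs)):
            cols["shape"][i] = v
        for i, v in zip(idx, _draw_categorical(u["margin"][idx],
                                               params.margin_probs)):
            cols["margin"][i] = v
        for i, v in zip(idx, _draw_categorical(u["distribution"][idx],
                                               params.distribution_probs)):
            cols["distribution"][i] = v
        for i, v in zip(idx, _draw_categorical(u["pattern"][idx],
                                               params.pattern_probs)):
            cols["pattern"][i] = v
        for i, v in zip(idx, _draw_categorical(u["birads"][idx],
                                               params.birads_probs)):
            birads[i] = int(v)
        adc[idx] = _truncnorm_ppf(u["adc"][idx], params.adc_mean,
                                  params.adc_sd, *params.adc_range)
        size[idx] = _trunc_lognorm_ppf(u["size"][idx], params.size_median_cm,
                                       params.size_sigma_log,
                                       *params.size_range_cm)

    records: list[LesionRecord] = []
    for i in range(n):
        pathology = Pathology.MALIGNANT if is_mal[i] else Pathology.BENIGN
        if not visible[i]:
            records.append(LesionRecord(
                lesion_id=f"syn{i:05d}", pathology=pathology,
                dwi_visible=False, size_cm=float(size[i]), birads=birads[i]))
            continue
        mass = bool(is_mass[i])
        records.append(LesionRecord(
            lesion_id=f"syn{i:05d}", pathology=pathology, dwi_visible=True,
            lesion_type=LesionType.MASS if mass else LesionType.NONMASS,
            shape=cols["shape"][i] if mass else None,
            margin=cols["margin"][i] if mass else None,
            distribution=None if mass else cols["distribution"][i],
            internal_pattern=cols["pattern"][i], adc=float(adc[i]),
            size_cm=float(size[i]), birads=birads[i]))
    return records


# ---------------------------------------------------------------------------
# Deterministic count-engineered cohort


# Joint (score, ADC<cutoff) counts per class among DWI-visible lesions,
# solved so that the score x ADC cross-table rows (21 = 7+14, 32 = 17+15,
# 88 = 68+20), the per-class ADC dichotomy (benign 6/23, malignant 86/26)
# and the confusion matrices of the qualitative (106/15), quantitative
# (86/23) and combination (104/21) readings all hold simultaneously.
_BENIGN_SCORE_ADC = {(1, True): 4, (1, False): 11,
                     (2, True): 2, (2, False): 10,
                     (3, True): 0, (3, False): 2}
_MALIGNANT_SCORE_ADC = {(1, True): 3, (1, False): 3,
                        (2, True): 15, (2, False): 5,
                        (3, True): 68, (3, False): 18}

# BI-RADS categories per (class, ADC stratum), matching category totals
# 12/28/104, the DCE operating point (111/112 and 11/32 at >= 4) and the
# DCE+ADC confusion matrix (109/26).
_BIRADS_BY_STRATUM = {
    (Pathology.BENIGN, True): [3] * 3 + [4] * 3,
    (Pathology.BENIGN, False): [3] * 5 + [4] * 18,
    (Pathology.MALIGNANT, True): [4] * 5 + [5] * 81,
    (Pathology.MALIGNANT, False): [3] * 1 + [4] * 2 + [5] * 23,
}

# Descriptor template producing a given score for a given lesion type.
_MASS_TEMPLATE = {
    1: (Shape.OVAL, Margin.CIRCUMSCRIBED, InternalPattern.HOMOGENEOUS),
    2: (Shape.IRREGULAR, Margin.IRREGULAR, InternalPattern.HOMOGENEOUS),
    3: (Shape.IRREGULAR, Margin.SPICULATED, InternalPattern.HETEROGENEOUS),
}
_NONMASS_TEMPLATE = {
    1: (Distribution.FOCAL, InternalPattern.HOMOGENEOUS),
    2: (Distribution.FOCAL, InternalPattern.HETEROGENEOUS),
    3: (Distribution.SEGMENTAL, InternalPattern.HETEROGENEOUS),
}

_ADC_VALUE = {  # (class, below-cutoff) -> representative ADC, 1e-3 mm^2/s
    (Pathology.BENIGN, True): 0.90, (Pathology.BENIGN, False): 1.20,
    (Pathology.MALIGNANT, True): 0.85, (Pathology.MALIGNANT, False): 1.10,
}


def engineered_study_cohort() -> list[LesionRecord]:
    """A deterministic 144-lesion synthetic cohort reproducing the published
    marginal tables of the reference study.

    Synthetic stand-in for the study's per-lesion dataset (which is not
    shipped): individual lesions are fictitious, but the joint counts of
    (pathology, visibility, qualitative score, ADC dichotomy at 1.0,
    BI-RADS category) reproduce every published marginal simultaneously —
    3/144 invisible (all benign; sizes 1.5, 0.6 and 0.4 cm), the score x
    ADC and BI-RADS x ADC cross-tables, and the confusion matrices of all
    five diagnostic readings.  The published tables force 2 benign score-3
    lesions even though the descriptor-frequency table shows no benign
    major descriptor; the cross-tables are honored.  Sizes are nominal
    (<=1 cm vs >1 cm placement only) and descriptors are canonical
    templates for each (type, score) pair, not frequency-calibrated.
    """
    records: list[LesionRecord] = []

    def build_class(pathology: Pathology, joint: dict, n_mass: int,
                    sizes: list[float], tag: str) -> None:
        lesions = [(score, below)
                   for (score, below), k in sorted(joint.items())
                   for _ in range(k)]
        # BI-RADS assigned within each ADC stratum in listing order
        stratum_iters = {below: iter(_BIRADS_BY_STRATUM[(pathology, below)])
                         for below in (True, False)}
        for j, (score, below) in enumerate(lesions):
            is_mass = j < n_mass
            if is_mass:
                shape, margin, pattern = _MASS_TEMPLATE[score]
                distribution = None
            else:
                distribution, pattern = _NONMASS_TEMPLATE[score]
                shape = margin = None
            records.append(LesionRecord(
                lesion_id=f"{tag}{j:03d}", pathology=pathology,
                dwi_visible=True,
                lesion_type=LesionType.MASS if is_mass else LesionType.NONMASS,
                shape=shape, margin=margin, distribution=distribution,
                internal_pattern=pattern,
                adc=_ADC_VALUE[(pathology, below)],
                size_cm=sizes[j], birads=next(stratum_iters[below])))

    benign_sizes = [0.8] * 23 + [1.5] * 6
    build_class(Pathology.BENIGN, _BENIGN_SCORE_ADC, n_mass=22,
                sizes=benign_sizes, tag="B")
    for j, size in enumerate((1.5, 0.6, 0.4)):  # the three invisible lesions
        records.append(LesionRecord(
            lesion_id=f"I{j:03d}", pathology=Pathology.BENIGN,
            dwi_visible=False, size_cm=size, birads=3))
    malignant_sizes = [0.9] * 20 + [2.0] * 92
    build_class(Pathology.MALIGNANT, _MALIGNANT_SCORE_ADC, n_mass=97,
                sizes=malignant_sizes, tag="M")
    assert len(records) == 144
    return records
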