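"""Seeded generator of synthetic crossover PK studies.

Emulates the data-generating structure of three single-dose methylphenidate
crossover studies of a delayed-release/extended-release (DR/ER) formulation:

* ``dose_proportionality`` -- 2x2 crossover, 20 vs 100 mg DR/ER, n = 20,
  evening dosing with the dense 0-48 h sampling schedule;
* ``evening_food_effect`` -- six-sequence 3x3 Latin square, 100 mg DR/ER
  under fed / sprinkled-on-applesauce / fasted conditions, n = 18;
* ``relative_bioavailability`` -- 2x2 crossover, 100 mg DR/ER vs 20 mg
  immediate-release (IR) methylphenidate, n = 12, IR on its own 0-24 h grid.

The population curves are one-compartment lag-time model curves whose
defaults put the DR/ER peak near 14 h post-dose with a terminal rate constant
of about 0.119 /h and essentially no exposure in the first 10 h (the
overnight window after an evening dose), and the IR peak near 1.5 h.
Between-subject variability is lognormal on ka/ke/scale with one draw per
subject shared across periods (subject is the random effect); an optional
occasion-level lognormal multiplier on scale creates within-subject
(intrasubject) variability of a configured size; residual assay error is
proportional + additive, clamped at zero, followed by the LLOQ -> 0 rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .compartmental import OneCompartmentParams, concentration
from .study_data import (
    DEFAULT_LLOQ,
    ConcTimeProfile,
    CrossoverStudy,
    DoseRegimen,
)

__all__ = [
    "DELAYED_SCHEDULE",
    "IMMEDIATE_SCHEDULE",
    "GeneratorConfig",
    "default_config",
    "generate_study",
    "generate_true_ratio_study",
]

#: Nominal sampling times (h post-dose) for the delayed/extended formulation;
#: the predose (-5 min) sample is recorded at time 0.
DELAYED_SCHEDULE: tuple[float, ...] = (
    0, 2, 4, 6, 8, 8.5, 9, 9.5, 10, 10.5, 11, 11.5, 12, 13, 14, 15, 16, 17,
    18, 19, 20, 22, 24, 36, 48,
)

#: Nominal sampling times for the immediate-release comparator.
IMMEDIATE_SCHEDULE: tuple[float, ...] = (
    0, 0.25, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6, 8, 10, 12, 14, 17, 20, 24,
)

# population parameters: DR/ER peak at ~14 h on the sampling grid, terminal
# slope ~0.119 /h, AUCinf ~170 ng.h/mL at 100 mg; IR peak at ~1.5 h
DELAYED_PARAMS = OneCompartmentParams(ka=0.42, ke=0.1192, tlag=10.0, scale=0.203)
# fed evening meal: absorption starts ~2.5 h later and peaks ~12% lower with
# unchanged total exposure -> longer lag, smaller ka, same ke and scale
DELAYED_FED_PARAMS = OneCompartmentParams(ka=0.285, ke=0.1192, tlag=12.5, scale=0.203)
IMMEDIATE_PARAMS = OneCompartmentParams(ka=1.6, ke=0.191, tlag=0.0, scale=0.306)
# DR/ER scale in the comparative-bioavailability study set so the true
# dose-normalized AUCinf ratio vs IR is 0.739 (colonic delivery loses ~26%
# of the dose): scale_DR = 0.739 * scale_IR * ke_DR / ke_IR
DELAYED_RELBA_PARAMS = OneCompartmentParams(
    ka=0.42, ke=0.1192, tlag=10.0, scale=0.739 * 0.306 * 0.1192 / 0.191
)

#: between-subject variability: lognormal CV% for ka/ke/scale; for tlag the
#: value is a truncated-normal SD in hours (floor 8 h -- the release delay is
#: the formulation's most tightly controlled feature)
DEFAULT_BSV_CV = {"ka": 30.0, "ke": 25.0, "scale": 30.0, "tlag": 0.5}
TLAG_FLOOR = 8.0


@dataclass(frozen=True)
class TreatmentSpec:
    """Regimen plus population model parameters for one treatment arm."""

    regimen: DoseRegimen
    params: OneCompartmentParams


@dataclass
class GeneratorConfig:
    design: str
    n_subjects: int
    treatments: dict[str, TreatmentSpec]
    bsv_cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BSV_CV))
    within_subject_cv: float = 0.0  # occasion-level lognormal CV% on scale
    residual: tuple[float, float] = (10.0, DEFAULT_LLOQ)  # (prop CV%, additive SD)
    lloq: float = DEFAULT_LLOQ
    schedule: dict[str, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.bsv_cv.values()):
            raise ValueError("BSV CVs must be >= 0")
        if self.within_subject_cv < 0 or any(r < 0 for r in self.residual):
            raise ValueError("noise settings must be >= 0")
        for code, spec in self.treatments.items():
            self.schedule.setdefault(
                code,
                IMMEDIATE_SCHEDULE
                if spec.regimen.formulation == "immediate_release"
                else DELAYED_SCHEDULE,
            )


def _sequences(design: str, codes: Sequence[str]) -> list[tuple[str, ...]]:
    if design == "two_by_two":
        a, b = codes
        return [(a, b), (b, a)]
    if design == "latin_square_3x3_6seq":
        import itertools

        return list(itertools.permutations(codes, 3))
    raise ValueError(f"cannot build sequences for design {design!r}")


def default_config(study: str, n_subjects: int | None = None, seed: int = 0) -> GeneratorConfig:
    """Generator configuration emulating one of the three study designs."""
    if study == "dose_proportionality":
        treatments = {
            "DR20": TreatmentSpec(
                DoseRegimen(20.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_PARAMS,
            ),
            "DR100": TreatmentSpec(
                DoseRegimen(100.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_PARAMS,
            ),
        }
        return GeneratorConfig(
            design="two_by_two",
            n_subjects=n_subjects or 20,
            treatments=treatments,
            seed=seed,
        )
    if study == "evening_food_effect":
        treatments = {
            "FED": TreatmentSpec(
                DoseRegimen(100.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_FED_PARAMS,
            ),
            "SPR": TreatmentSpec(
                DoseRegimen(100.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_PARAMS,
            ),
            "FST": TreatmentSpec(
                DoseRegimen(100.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_PARAMS,
            ),
        }
        return GeneratorConfig(
            design="latin_square_3x3_6seq",
            n_subjects=n_subjects or 18,
            treatments=treatments,
            seed=seed,
        )
    if study == "relative_bioavailability":
        treatments = {
            "DR100": TreatmentSpec(
                DoseRegimen(100.0, "delayed_extended", admin_clock_time="21:00"),
                DELAYED_RELBA_PARAMS,
            ),
            "IR20": TreatmentSpec(
                DoseRegimen(20.0, "immediate_release", admin_clock_time="08:00"),
                IMMEDIATE_PARAMS,
            ),
        }
        return GeneratorConfig(
            design="two_by_two",
            n_subjects=n_subjects or 12,
            treatments=treatments,
            seed=seed,
        )
    raise ValueError(f"unknown study label {study!r}")


def _lognormal_sigma(cv_pct: float) -> float:
    return math.sqrt(math.log(1.0 + (cv_pct / 100.0) ** 2))


def _subject_params(
    etas: Mapping[str, float], pop: OneCompartmentParams, bsv_cv: Mapping[str, float]
) -> OneCompartmentParams:
    """Apply one subject's standard-normal etas to a population vector.

    The etas are drawn once per subject and shared across treatments and
    periods -- the subject random effect of the bioequivalence model.
    Lognormal with median = population value, so geometric-mean treatment
    contrasts of the population curves are preserved exactly.
    """
    draws = {
        name: getattr(pop, name)
        * math.exp(_lognormal_sigma(bsv_cv.get(name, 0.0)) * etas[name])
        for name in ("ka", "ke", "scale")
    }
    sd = bsv_cv.get("tlag", 0.0)
    if pop.tlag > 0 and sd > 0:
        # truncated-normal jitter: the release delay never dips below 8 h
        a = (TLAG_FLOOR - pop.tlag) / sd
        tlag = float(stats.truncnorm.ppf(etas["tlag_u"], a, np.inf, loc=pop.tlag, scale=sd))
    else:
        tlag = pop.tlag
    return OneCompartmentParams(ka=draws["ka"], ke=draws["ke"], tlag=tlag, scale=draws["scale"])


def generate_study(config: GeneratorConfig) -> CrossoverStudy:
    """Generate a fully reproducible crossover study from the config.

    Draw order is fixed: for each subject (in id order) the parameter vector
    is drawn once and shared across that subject's periods; then, period by
    period, the occasion multiplier and the per-sample residual errors.
    """
    codes = sorted(config.treatments)
    seqs = _sequences(config.design, codes)
    if config.n_subjects % len(seqs) != 0:
        raise ValueError(
            f"n_subjects={config.n_subjects} not divisible by {len(seqs)} sequences"
        )
    rng = np.random.default_rng(config.seed)
    prop_cv, add_sd = config.residual
    sigma_w = _lognormal_sigma(config.within_subject_cv)

    profiles: list[ConcTimeProfile] = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        seq = seqs[i % len(seqs)]
        subj = f"S{i + 1:0{width}d}"
        # subject-level draws first; one eta vector per subject, shared
        # across treatments (no subject-by-treatment interaction)
        etas = {name: float(rng.standard_normal()) for name in ("ka", "ke", "scale")}
        etas["tlag_u"] = float(rng.uniform())
        base = {
            code: _subject_params(etas, config.treatments[code].params, config.bsv_cv)
            for code in codes
        }
        seq_label = "-".join(seq) if any(len(c) > 1 for c in seq) else "".join(seq)
        for period, code in enumerate(seq, start=1):
            par = base[code]
            if sigma_w:
                par = replace(par, scale=par.scale * math.exp(sigma_w * rng.standard_normal()))
            times = np.asarray(config.schedule[code], dtype=float)
            conc = np.asarray(
                concentration(par, config.treatments[code].regimen.dose_mg, times)
            )
            # assay error applies to quantifiable drug only: samples with no
            # drug (predose, pre-lag) read back as exact zeros (sub-LLOQ)
            drug = conc > 0
            if prop_cv:
                conc[drug] *= 1.0 + (prop_cv / 100.0) * rng.standard_normal(int(drug.sum()))
            if add_sd:
                conc[drug] += add_sd * rng.standard_normal(int(drug.sum()))
            conc = np.clip(conc, 0.0, None)
            profiles.append(
                ConcTimeProfile(
                    subject_id=subj,
                    treatment=code,
                    period=period,
                    sequence=seq_label,
                    times=tuple(times.tolist()),
                    concentrations=tuple(conc.tolist()),
                    lloq=config.lloq,
                )
            )
    return CrossoverStudy(
        design=config.design,
        treatments={c: config.treatments[c].regimen for c in codes},
        profiles=profiles,
        sampling_schedule={c: tuple(config.schedule[c]) for c in codes},
    )


def generate_true_ratio_study(
    config: GeneratorConfig, metric: str, true_ratio: float
) -> CrossoverStudy:
    """Two-treatment study whose true geometric mean ratio is ``true_ratio``.

    The test treatment's population curve is the reference curve scaled by
    ``true_ratio``, so every scale-linear exposure metric (Cmax, AUC0-t,
    AUC0-inf and their dose-normalized versions -- including ``metric``) has
    geometric mean ratio exactly ``true_ratio`` between the arms.  Subject
    parameter draws are shared between arms, and BSV/occasion noise is
    lognormal with median preserved, so the truth is exact, which makes this
    the calibration harness for the bioequivalence module (CI coverage,
    power, bias).
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    codes = sorted(config.treatments)
    if len(codes) != 2:
        raise ValueError("true-ratio studies are two-treatment by construction")
    # lexicographically first code is the reference arm, second is the test;
    # the test arm inherits the reference regimen and schedule so its
    # population curve is exactly true_ratio times the reference curve
    ref_code, test_code = codes[0], codes[1]
    ref_spec = config.treatments[ref_code]
    treatments = {ref_code: ref_spec, test_code: ref_spec}
    codes_sorted = codes
    base_cfg = replace(
        config,
        treatments=treatments,
        schedule={c: config.schedule.get(ref_code, DELAYED_SCHEDULE) for c in codes},
    )
    # generate both arms from the identical reference curve, then rescale the
    # test arm's concentrations so the ratio survives the multiplicative noise
    study = generate_study(base_cfg)
    rescaled = []
    for p in study.profiles:
        if p.treatment == test_code:
            conc = np.asarray(p.concentrations) * true_ratio
            rescaled.append(
                ConcTimeProfile(
                    subject_id=p.subject_id,
                    treatment=p.treatment,
                    period=p.period,
                    sequence=p.sequence,
                    times=p.times,
                    concentrations=tuple(conc.tolist()),
                    lloq=0.0,  # rescaling after LLOQ would break exactness
                )
            )
        else:
            rescaled.append(p)
    return CrossoverStudy(
        design=study.design,
        treatments={c: treatments[c].regimen for c in codes_sorted},
        profiles=rescaled,
        sampling_schedule=study.sampling_schedule,
    )
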