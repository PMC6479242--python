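"""Domain types and I/O for crossover concentration-time study datasets.

A study is stored on disk as a long-format CSV (one row per observation,
columns ``subject, sequence, period, treatment, time_h, conc_ng_ml``), the
NONMEM-style convention for PK datasets: UTF-8, comma-separated, dot decimal,
times in hours post-dose.  Design metadata (treatment regimens, nominal
sampling schedules) travels in a separate YAML/JSON config.

Concentrations below the lower limit of quantitation (LLOQ, 0.02 ng/mL by
default) are replaced by exactly 0 before any analysis, mirroring standard
bioanalytical reporting for plasma methylphenidate; the raw sub-LLOQ value is
not retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_LLOQ",
    "SchemaError",
    "IntegrityError",
    "ConcTimeProfile",
    "DoseRegimen",
    "CrossoverStudy",
    "apply_lloq",
    "read_study",
    "write_study",
    "load_design_config",
]

#: Lower limit of quantitation of the plasma assay, ng/mL.
DEFAULT_LLOQ = 0.02

REQUIRED_COLUMNS = ("subject", "sequence", "period", "treatment", "time_h", "conc_ng_ml")

DESIGNS = ("two_by_two", "latin_square_3x3_6seq", "parallel")
FORMULATIONS = ("delayed_extended", "immediate_release")


class SchemaError(ValueError):
    """The input table does not have the expected columns/config keys."""


class IntegrityError(ValueError):
    """The input table violates structural constraints (duplicates, types)."""


def apply_lloq(concentrations: Sequence[float], lloq: float = DEFAULT_LLOQ) -> np.ndarray:
    """Replace every concentration strictly below ``lloq`` with exactly 0.

    Idempotent: 0 is itself below the LLOQ and maps to 0 again.
    """
    conc = np.asarray(concentrations, dtype=float).copy()
    conc[conc < lloq] = 0.0
    return conc


@dataclass(frozen=True)
class ConcTimeProfile:
    """One subject x treatment-period plasma concentration-time series.

    ``times`` are hours post-dose (the predose sample is recorded at time 0);
    ``concentrations`` are ng/mL after LLOQ substitution.
    """

    subject_id: str
    treatment: str
    period: int
    sequence: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.size != conc.size:
            raise ValueError(
                f"profile {self.subject_id}/{self.treatment}: "
                f"{times.size} times vs {conc.size} concentrations"
            )
        if times.size and times[0] < 0:
            raise ValueError("negative time post-dose")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        if int(self.period) != self.period or self.period < 1:
            raise IntegrityError(f"period must be a positive integer, got {self.period!r}")
        object.__setattr__(self, "times", tuple(times.tolist()))
        object.__setattr__(self, "concentrations", tuple(apply_lloq(conc, self.lloq).tolist()))
        object.__setattr__(self, "period", int(self.period))

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def conc_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)


@dataclass(frozen=True)
class DoseRegimen:
    """Dose and dosing-interval metadata for one treatment arm."""

    dose_mg: float
    formulation: str = "delayed_extended"
    interval_tau_h: float = 24.0
    n_doses: int = 1
    admin_clock_time: str | None = None  # report-only label, e.g. "21:00"

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be > 0")
        if self.interval_tau_h <= 0:
            raise ValueError("interval_tau_h must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")


@dataclass
class CrossoverStudy:
    """A crossover (or parallel) PK study: design, regimens and profiles."""

    design: str
    treatments: dict[str, DoseRegimen]
    profiles: list[ConcTimeProfile]
    sampling_schedule: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        for p in self.profiles:
            key = (p.subject_id, p.period)
            if key in seen:
                raise IntegrityError(f"subject {p.subject_id} appears twice in period {p.period}")
            seen.add(key)
            # a subject's treatment in period k must match position k of its sequence
            seq = [s.strip() for s in p.sequence.split("-")] if "-" in p.sequence else list(p.sequence)
            if len(seq) >= p.period and seq[p.period - 1] != p.treatment:
                raise IntegrityError(
                    f"subject {p.subject_id}: treatment {p.treatment!r} in period "
                    f"{p.period} contradicts sequence {p.sequence!r}"
                )
            sched = self.sampling_schedule.get(p.treatment)
            if sched is not None and not set(np.round(p.times, 6)) <= set(np.round(sched, 6)):
                raise IntegrityError(
                    f"subject {p.subject_id}/{p.treatment}: observed times outside "
                    "the nominal sampling schedule"
                )

    @property
    def subjects(self) -> list[str]:
        return sorted({p.subject_id for p in self.profiles})

    def profiles_for(self, treatment: str) -> list[ConcTimeProfile]:
        return [p for p in self.profiles if p.treatment == treatment]

    def to_frame(self) -> pd.DataFrame:
        """Long-format observation table (one row per sample)."""
        rows = []
        for p in sorted(self.profiles, key=lambda q: (q.subject_id, q.period)):
            for t, c in zip(p.times, p.concentrations):
                rows.append((p.subject_id, p.sequence, p.period, p.treatment, t, c))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _sequence_string(treatments_in_order: Iterable[str]) -> str:
    codes = list(treatments_in_order)
    if all(len(c) == 1 for c in codes):
        return "".join(codes)
    return "-".join(codes)


def load_design_config(path: str | Path) -> dict:
    """Load a YAML or JSON design-metadata config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _regimens_from_schema(schema: Mapping | None, codes: Iterable[str]) -> dict[str, DoseRegimen]:
    treatments: dict[str, DoseRegimen] = {}
    spec = (schema or {}).get("treatments", {})
    for code in codes:
        if code in spec:
            entry = dict(spec[code])
            treatments[code] = DoseRegimen(
                dose_mg=float(entry["dose_mg"]),
                formulation=entry.get("formulation", "delayed_extended"),
                interval_tau_h=float(entry.get("interval_tau_h", 24.0)),
                n_doses=int(entry.get("n_doses", 1)),
                admin_clock_time=entry.get("admin_clock_time"),
            )
        else:
            # placeholder regimen: analyses that need the dose (DN metrics)
            # require real metadata, everything else works
            treatments[code] = DoseRegimen(dose_mg=1.0, formulation="immediate_release")
    return treatments


def read_study(path: str | Path, schema: Mapping | str | Path | None = None) -> CrossoverStudy:
    """Read a long-format concentration-time CSV into a validated study.

    Parameters
    ----------
    path
        CSV with columns ``subject, sequence, period, treatment, time_h,
        conc_ng_ml``.
    schema
        Optional design config (mapping, or path to YAML/JSON) with keys
        ``design``, ``treatments`` (code -> dose/formulation/tau), ``lloq``
        and ``sampling_schedule``.  Without it the design is inferred from
        the number of treatments and placeholder 1-mg regimens are used.

    The LLOQ -> 0 substitution is applied on read; rows are sorted by
    subject/period/time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is not None and not isinstance(schema, Mapping):
        schema = load_design_config(schema)

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df):
        periods = pd.to_numeric(df["period"], errors="coerce")
        if periods.isna().any() or (periods != periods.round()).any():
            bad = df["period"][periods.isna() | (periods != periods.round())].iloc[0]
            raise IntegrityError(f"non-integer period value {bad!r}")
        df["period"] = periods.astype(int)
        if df.duplicated(["subject", "period", "time_h"]).any():
            dup = df[df.duplicated(["subject", "period", "time_h"])].iloc[0]
            raise IntegrityError(
                f"duplicate observation for subject {dup['subject']!r}, "
                f"period {dup['period']}, time {dup['time_h']}"
            )
        if (df["time_h"] < 0).any():
            raise ValueError("negative time_h in input")
        if (df["conc_ng_ml"] < 0).any():
            raise ValueError("negative conc_ng_ml in input")

    lloq = float((schema or {}).get("lloq", DEFAULT_LLOQ))
    df = df.sort_values(["subject", "period", "time_h"], kind="mergesort")

    profiles: list[ConcTimeProfile] = []
    for (subj, period), grp in df.groupby(["subject", "period"], sort=True):
        treatments = grp["treatment"].unique()
        if len(treatments) != 1:
            raise IntegrityError(f"subject {subj!r} period {period}: multiple treatments")
        sequences = grp["sequence"].unique()
        if len(sequences) != 1:
            raise IntegrityError(f"subject {subj!r} period {period}: multiple sequences")
        profiles.append(
            ConcTimeProfile(
                subject_id=str(subj),
                treatment=str(treatments[0]),
                period=int(period),
                sequence=str(sequences[0]),
                times=tuple(grp["time_h"].astype(float)),
                concentrations=tuple(grp["conc_ng_ml"].astype(float)),
                lloq=lloq,
            )
        )

    codes = sorted({p.treatment for p in profiles}) or sorted((schema or {}).get("treatments", {}))
    design = (schema or {}).get("design")
    if design is None:
        design = "latin_square_3x3_6seq" if len(codes) == 3 else "two_by_two"
    schedule = {
        k: tuple(float(t) for t in v)
        for k, v in ((schema or {}).get("sampling_schedule") or {}).items()
    }
    return CrossoverStudy(
        design=design,
        treatments=_regimens_from_schema(schema, codes),
        profiles=profiles,
        sampling_schedule=schedule,
    )


def write_study(study: CrossoverStudy, path: str | Path) -> None:
    """Write the study's observations as a long-format CSV.

    Floats are written with ``repr`` precision so that
    ``read_study(write_study(s))`` reproduces times and concentrations
    bit-identically.
    """
    path = Path(path)
    df = study.to_frame()
    # shortest round-trip decimal text so floats survive read/write exactly
    for col in ("time_h", "conc_ng_ml"):
        df[col] = df[col].map(repr)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write study to {path}: {exc}") from exc
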