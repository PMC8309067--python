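"""Dataset model and NONMEM-style CSV I/O.

The in-memory containers mirror a conventional pop-PK data layout: one
dose event and a series of timed plasma-concentration observations per
subject, plus a single binary formulation covariate.  Two contrasts are
supported:

* ``FREE_VS_NANO`` — free drug solution coded 0, any nanoformulation
  (nanoparticle or nanoemulsion) coded 1.
* ``NP_VS_NE`` — nanoparticles coded 0, nanoemulsions coded 1; free
  solution subjects are not allowed under this contrast.

Units are fixed package-wide: time in hours, concentration in ng/mL,
dose in mg/kg.  The mg/L -> ng/mL factor of 1000 is applied inside the
structural predictions, never in stored data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Route",
    "Formulation",
    "Contrast",
    "ObservationRow",
    "DoseEvent",
    "SubjectRecord",
    "PKDataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
]

CSV_COLUMNS = ["ID", "TIME", "DV", "AMT", "ROUTE", "FORM"]


class DatasetFormatError(ValueError):
    """Raised when a CSV file does not follow the expected dialect."""


class DatasetValidationError(ValueError):
    """Raised when dataset content violates a structural invariant."""


class Route(str, enum.Enum):
    IV_BOLUS = "iv_bolus"
    ORAL = "oral"


class Formulation(str, enum.Enum):
    FREE = "FREE"
    NANOPARTICLE = "NANOPARTICLE"
    NANOEMULSION = "NANOEMULSION"


class Contrast(str, enum.Enum):
    FREE_VS_NANO = "FREE_VS_NANO"
    NP_VS_NE = "NP_VS_NE"


#: formulation -> covariate code under each contrast; None = not allowed
_FORM_CODE = {
    Contrast.FREE_VS_NANO: {
        Formulation.FREE: 0,
        Formulation.NANOPARTICLE: 1,
        Formulation.NANOEMULSION: 1,
    },
    Contrast.NP_VS_NE: {
        Formulation.FREE: None,
        Formulation.NANOPARTICLE: 0,
        Formulation.NANOEMULSION: 1,
    },
}


def form_code(formulation: Formulation, contrast: Contrast) -> int:
    """Binary covariate code of ``formulation`` under ``contrast``."""
    code = _FORM_CODE[Contrast(contrast)][Formulation(formulation)]
    if code is None:
        raise DatasetValidationError(
            f"formulation {formulation} is not allowed under contrast {contrast}"
        )
    return code


@dataclass(frozen=True)
class ObservationRow:
    subject_id: str
    time: float          # h
    conc: float          # ng/mL, strictly positive

    def __post_init__(self) -> None:
        if not self.conc > 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: non-positive concentration "
                f"{self.conc} at t={self.time} h (log-scale error model "
                "requires DV > 0)"
            )
        if self.time < 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: negative time {self.time}"
            )


@dataclass(frozen=True)
class DoseEvent:
    subject_id: str
    time: float          # h (0 for all study doses)
    amount: float        # mg/kg
    route: Route

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: dose amount must be > 0, "
                f"got {self.amount}"
            )
        object.__setattr__(self, "route", Route(self.route))


@dataclass
class SubjectRecord:
    subject_id: str
    formulation: Formulation
    form_code: int
    dose_events: list[DoseEvent] = field(default_factory=list)
    observations: list[ObservationRow] = field(default_factory=list)

    @property
    def times(self):
        return [o.time for o in self.observations]

    @property
    def concs(self):
        return [o.conc for o in self.observations]

    @property
    def route(self) -> Route:
        return self.dose_events[0].route

    @property
    def dose(self) -> float:
        return self.dose_events[0].amount

    def validate(self) -> None:
        if not self.dose_events:
            raise DatasetValidationError(
                f"subject {self.subject_id}: no dose event"
            )
        if len(self.observations) < 2:
            raise DatasetValidationError(
                f"subject {self.subject_id}: needs >= 2 observations, "
                f"has {len(self.observations)}"
            )
        t = self.times
        for a, b in zip(t, t[1:]):
            if not b > a:
                raise DatasetValidationError(
                    f"subject {self.subject_id}: observation times not "
                    f"strictly increasing ({a} -> {b})"
                )


@dataclass
class PKDataset:
    subjects: list[SubjectRecord]
    contrast: Contrast
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contrast = Contrast(self.contrast)

    def validate(self) -> None:
        if not self.subjects:
            raise DatasetValidationError("dataset has no subjects")
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise DatasetValidationError(
                    f"duplicate subject id {s.subject_id!r}"
                )
            seen.add(s.subject_id)
            s.validate()
            expected = form_code(s.formulation, self.contrast)
            if s.form_code != expected:
                raise DatasetValidationError(
                    f"subject {s.subject_id}: form_code {s.form_code} "
                    f"inconsistent with {s.formulation.value} under "
                    f"{self.contrast.value} (expected {expected})"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def arms(self) -> dict[tuple[Formulation, Route], list[SubjectRecord]]:
        """Group subjects by (formulation, route) study arm."""
        out: dict[tuple[Formulation, Route], list[SubjectRecord]] = {}
        for s in self.subjects:
            out.setdefault((s.formulation, s.route), []).append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for d in s.dose_events:
                rows.append(
                    dict(ID=s.subject_id, TIME=d.time, DV=None,
                         AMT=d.amount, ROUTE=d.route.value,
                         FORM=s.formulation.value)
                )
            for o in s.observations:
                rows.append(
                    dict(ID=s.subject_id, TIME=o.time, DV=o.conc,
                         AMT=None, ROUTE=s.route.value,
                         FORM=s.formulation.value)
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_route(token: str, subject_id: str) -> Route:
    try:
        return Route(token)
    except ValueError:
        raise DatasetValidationError(
            f"subject {subject_id}: unknown ROUTE token {token!r} "
            f"(expected one of {[r.value for r in Route]})"
        ) from None


def read_dataset(path, contrast: Contrast | str) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`.

    Dose rows carry AMT > 0 and a blank DV; observation rows carry
    DV > 0 and a blank AMT.  Rows within a subject are sorted by time,
    preserving file order among ties.
    """
    contrast = Contrast(contrast)
    df = pd.read_csv(path, dtype={"ID": str, "ROUTE": str, "FORM": str},
                     float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {CSV_COLUMNS}"
        )
    subjects: list[SubjectRecord] = []
    for sid, grp in df.groupby("ID", sort=False):
        grp = grp.sort_values("TIME", kind="stable")
        form_tokens = grp["FORM"].dropna().unique()
        if len(form_tokens) != 1:
            raise DatasetValidationError(
                f"subject {sid}: FORM must be constant, got {form_tokens}"
            )
        try:
            formulation = Formulation(form_tokens[0])
        except ValueError:
            raise DatasetValidationError(
                f"subject {sid}: unknown FORM token {form_tokens[0]!r}"
            ) from None
        for token in grp["ROUTE"].dropna().unique():
            _parse_route(token, str(sid))
        rec = SubjectRecord(
            subject_id=str(sid),
            formulation=formulation,
            form_code=form_code(formulation, contrast),
        )
        for _, row in grp.iterrows():
            amt = row["AMT"]
            dv = row["DV"]
            if pd.notna(amt):
                rec.dose_events.append(
                    DoseEvent(str(sid), float(row["TIME"]), float(amt),
                              _parse_route(row["ROUTE"], str(sid)))
                )
            else:
                if pd.isna(dv):
                    raise DatasetValidationError(
                        f"subject {sid}: row at t={row['TIME']} has "
                        "neither AMT nor DV"
                    )
                if not float(dv) > 0:
                    raise DatasetValidationError(
                        f"subject {sid}: DV={dv} at t={row['TIME']} h "
                        "must be strictly positive on an observation row"
                    )
                rec.observations.append(
                    ObservationRow(str(sid), float(row["TIME"]), float(dv))
                )
        subjects.append(rec)
    ds = PKDataset(subjects=subjects, contrast=contrast,
                   metadata={"source": str(path)})
    ds.validate()
    return ds


def write_dataset(dataset: PKDataset, path) -> None:
    """Write ``dataset`` as a NONMEM-style CSV readable by :func:`read_dataset`.

    Inapplicable cells (DV on dose rows, AMT on observation rows) are
    left blank, not zero-filled.
    """
    dataset.validate()
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
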