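"""Derived echocardiographic parameters for rodent phenotyping.

From raw B-mode volumes (LVEDV, LVESV), M-mode diameters and diastolic
wall thicknesses (LVEDD, LVESD, LVAWTd, LVPWTd) and heart rate, compute:

    LVSV   = LVEDV - LVESV                      (stroke volume)
    LVEF   = LVSV / LVEDV * 100                 (ejection fraction, %)
    LVCO   = heart_rate * LVSV / 1000           (cardiac output)
    LVFS   = (LVEDD - LVESD) / LVEDD * 100      (fractional shortening, %)
    RWT    = 2 * LVPWTd / LVEDD                 (relative wall thickness)
    LVMass = 1.04 * (((LVEDD + LVAWTd + LVPWTd)^3 - LVEDD^3) * 0.8 + 0.6)

LVMass is the modified cubic formula: 1.04 is the myocardial density
(g/mL when lengths are in cm), and the cube of the epicardial minus the
cube of the endocardial diameter approximates the myocardial shell
volume.  Units pass through unchanged; cm inputs give grams.  The
diastolic internal diameter (sometimes written LVIDd) is LVEDD.

Group comparison uses the unpaired Student's t-test by default (the
convention for echo panels), via :mod:`gpcrscreen.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import two_group_test

__all__ = ["EchoRecord", "EchoDerived", "derive", "derive_table", "compare_groups"]

log = logging.getLogger(__name__)

DERIVED_PARAMS = ("LVSV", "LVEF", "LVCO", "LVFS", "RWT", "LVMass")


@dataclass(frozen=True)
class EchoRecord:
    """Raw echocardiographic measurements for one animal.

    Volumes (LVEDV, LVESV) and lengths (LVEDD, LVESD, LVAWTd, LVPWTd) are
    in caller-chosen consistent units; heart_rate in beats/min.
    """

    animal: str
    group: str
    heart_rate: float
    LVEDV: float
    LVESV: float
    LVEDD: float
    LVESD: float
    LVAWTd: float
    LVPWTd: float

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ValidationError(f"{self.animal}: heart_rate must be > 0")
        if not self.LVEDV > self.LVESV >= 0:
            raise ValidationError(f"{self.animal}: need LVEDV > LVESV >= 0")
        for name in ("LVEDD", "LVESD", "LVAWTd", "LVPWTd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.animal}: {name} must be > 0")


@dataclass(frozen=True)
class EchoDerived:
    animal: str
    group: str
    LVSV: float
    LVEF: float
    LVCO: float
    LVFS: float
    RWT: float
    LVMass: float


def derive(record: EchoRecord) -> EchoDerived:
    """Compute all derived parameters from one raw record (validates first)."""
    record.validate()
    lvsv = record.LVEDV - record.LVESV
    lvef = lvsv / record.LVEDV * 100.0
    lvco = record.heart_rate * lvsv / 1000.0
    lvfs = (record.LVEDD - record.LVESD) / record.LVEDD * 100.0
    rwt = 2.0 * record.LVPWTd / record.LVEDD
    outer = record.LVEDD + record.LVAWTd + record.LVPWTd
    lvmass = 1.04 * ((outer**3 - record.LVEDD**3) * 0.8 + 0.6)
    return EchoDerived(record.animal, record.group, lvsv, lvef, lvco, lvfs, rwt, lvmass)


def derive_table(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`derive` row-wise to a raw measurements table.

    Expects columns animal, group, heart_rate, LVEDV, LVESV, LVEDD, LVESD,
    LVAWTd, LVPWTd.  Rows failing validation are skipped with a log entry;
    the returned table has one row per valid animal.
    """
    required = ["animal", "group", "heart_rate", "LVEDV", "LVESV",
                "LVEDD", "LVESD", "LVAWTd", "LVPWTd"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValidationError(f"echo table missing columns: {missing}")
    rows = []
    for _, row in records.iterrows():
        rec = EchoRecord(**{c: row[c] for c in required})
        try:
            rows.append(derive(rec).__dict__)
        except ValidationError as exc:
            log.warning("skipping echo record: %s", exc)
    return pd.DataFrame(rows)


def compare_groups(
    records: pd.DataFrame,
    mode: str = "force_t",
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-parameter two-group comparison of derived echo values.

    Derives every record, then tests each parameter between the two groups
    (Student's t by default), reporting mean +/- SEM per group, the mean
    difference (group2 - group1) and the p-value.  Parameters with fewer
    than 3 valid animals in a group are skipped with a flag.
    """
    derived = derive_table(records)
    if derived.empty:
        raise ValidationError("no valid echo records")
    labels = pd.unique(derived["group"])
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(labels)}")
    if group_order is None:
        group_order = (str(labels[0]), str(labels[1]))
    g1, g2 = group_order

    rows = []
    for param in DERIVED_PARAMS:
        a = derived.loc[derived["group"] == g1, param].to_numpy(dtype=float)
        b = derived.loc[derived["group"] == g2, param].to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            rows.append({"parameter": param, "skipped": True})
            continue
        res = two_group_test(a, b, mode=mode)
        rows.append(
            {
                "parameter": param,
                "mean_group1": a.mean(),
                "sem_group1": a.std(ddof=1) / np.sqrt(a.size),
                "mean_group2": b.mean(),
                "sem_group2": b.std(ddof=1) / np.sqrt(b.size),
                "mean_diff": res.mean_diff,
                "p": res.p,
                "test_used": res.test_used,
                "significant": res.significant,
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
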