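"""Comparative-Ct (delta-delta-Ct) relative quantification for qPCR plates.

The comparative-Ct method expresses a target gene's abundance in a sample
relative to an endogenous reference gene (Gapdh for mouse tissue) and a
calibrator sample:

    dCt(s)  = mean Ct_target(s) - mean Ct_reference(s)
    ddCt(s) = dCt(s) - dCt(calibrator)
    RQ(s)   = 2 ** (-ddCt(s))

Replicate Ct values are aggregated by arithmetic mean (standard practice;
no outlier rejection).  Amplification efficiency is fixed at 2.0 (perfect
per-cycle doubling), the assumption under which the method is exact.
RQ is always positive, equals 1 for the calibrator, and is invariant
under any global Ct offset applied equally to target and reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .expression_io import _atomic_write_text, _fmt

__all__ = [
    "QpcrError",
    "IncompletePlateError",
    "CtRangeError",
    "QpcrPlate",
    "read_plate",
    "write_plate_summary",
    "delta_ct",
    "relative_quantity",
    "plate_summary",
]

CT_RANGE_DEFAULT = (0.0, 45.0)


class QpcrError(Exception):
    pass


class IncompletePlateError(QpcrError):
    """A sample lacks wells for the target or the reference gene."""


class CtRangeError(QpcrError):
    """A Ct value is non-finite or outside the plausible cycle range."""


@dataclass
class QpcrPlate:
    """Triplicate (or any-replicate) Ct values per (sample, gene).

    ``wells`` has columns sample_id, gene_id, ct (cycles) and optionally
    replicate.  A declared reference gene and calibrator sample anchor the
    relative quantification; the calibrator is always an explicit choice,
    never defaulted.
    """

    wells: pd.DataFrame
    reference_gene: str
    calibrator_sample: str
    ct_range: tuple[float, float] = field(default=CT_RANGE_DEFAULT)

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise QpcrError(f"plate table missing column(s) {sorted(missing)}")
        self.wells = self.wells.copy()
        self.wells["ct"] = self.wells["ct"].astype(float)
        lo, hi = self.ct_range
        for row in self.wells.itertuples():
            if not math.isfinite(row.ct) or not lo <= row.ct <= hi:
                raise CtRangeError(
                    f"Ct {row.ct} out of range [{lo}, {hi}] in well "
                    f"(sample {row.sample_id!r}, gene {row.gene_id!r})")
        if self.calibrator_sample not in set(self.wells["sample_id"]):
            raise IncompletePlateError(
                f"calibrator sample {self.calibrator_sample!r} absent from plate")
        for sample in self.samples:
            genes = set(self.wells.loc[self.wells["sample_id"] == sample,
                                       "gene_id"])
            if self.reference_gene not in genes:
                raise IncompletePlateError(
                    f"sample {sample!r} has no wells for reference gene "
                    f"{self.reference_gene!r}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.wells["sample_id"]))

    def mean_ct(self, sample: str, gene: str) -> float:
        sel = self.wells[(self.wells["sample_id"] == sample)
                         & (self.wells["gene_id"] == gene)]
        if sel.empty:
            raise IncompletePlateError(
                f"no wells for gene {gene!r} in sample {sample!r}")
        return float(sel["ct"].mean())

    def sd_ct(self, sample: str, gene: str) -> float:
        sel = self.wells[(self.wells["sample_id"] == sample)
                         & (self.wells["gene_id"] == gene)]
        if len(sel) < 2:
            return 0.0
        return float(sel["ct"].std(ddof=1))


def read_plate(path, reference_gene: str, calibrator_sample: str,
               ct_range: tuple[float, float] = CT_RANGE_DEFAULT) -> QpcrPlate:
    """Read a plate TSV with columns sample_id, gene_id, ct[, replicate]."""
    wells = pd.read_csv(path, sep="\t",
                        dtype={"sample_id": str, "gene_id": str})
    return QpcrPlate(wells, reference_gene, calibrator_sample, ct_range)


def delta_ct(plate: QpcrPlate, target_gene: str, sample: str) -> float:
    """dCt = mean target Ct minus mean reference Ct for one sample."""
    return (plate.mean_ct(sample, target_gene)
            - plate.mean_ct(sample, plate.reference_gene))


def relative_quantity(plate: QpcrPlate, target_gene: str, sample: str) -> float:
    """RQ = 2^(-ddCt) of the target in ``sample`` versus the calibrator."""
    ddct = (delta_ct(plate, target_gene, sample)
            - delta_ct(plate, target_gene, plate.calibrator_sample))
    return 2.0 ** (-ddct)


def plate_summary(plate: QpcrPlate, target_gene: str) -> pd.DataFrame:
    """Per-sample RQ with the replicate SD of dCt propagated from the wells.

    The dCt spread combines target and reference replicate SDs in
    quadrature (independent wells).  One row per sample, plate order.
    """
    rows = []
    for sample in plate.samples:
        sd = math.hypot(plate.sd_ct(sample, target_gene),
                        plate.sd_ct(sample, plate.reference_gene))
        rows.append({
            "sample_id": sample,
            "rq": relative_quantity(plate, target_gene, sample),
            "delta_ct_sd": sd,
        })
    return pd.DataFrame(rows, columns=["sample_id", "rq", "delta_ct_sd"])


def write_plate_summary(summary: pd.DataFrame, path) -> None:
    lines = ["sample_id\trq\tdelta_ct_sd"]
    for row in summary.itertuples():
        lines.append(f"{row.sample_id}\t{_fmt(row.rq)}\t{_fmt(row.delta_ct_sd)}")
    _atomic_write_text(path, "\n".join(lines) + "\n")
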