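"""Droplet digital PCR quantification of %LOY.

A two-channel assay counts droplets positive for an X-chromosome
reference target (AMELX) and a Y target (AMELY).  With template copies
Poisson-distributed across droplets, the mean copies per droplet for a
channel is recovered from the positive fraction by the limiting-dilution
correction ``lambda = -ln(1 - n_pos / n_total)``, and the fraction of
genomes lacking Y is

    %LOY = 100 * (1 - lambda_Y / lambda_X).

Concentrations are ``lambda / droplet_volume`` (copies/uL); the volume
cancels in the ratio, so %LOY is volume-invariant.  Sampling noise can
push the point estimate slightly negative; such values are reported raw
and flagged, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DropletWell, ValidationError, load_patient_loy_table

logger = logging.getLogger("mosaicloy")

DEFAULT_DETECTION_THRESHOLD_PCT = 5.0


class SaturationError(ValidationError):
    """All droplets positive: the Poisson inversion is undefined."""


@dataclass
class DdpcrQuant:
    """Derived quantities for one well.

    ``pct_loy`` is clamped to [-100, 100]; ``pct_loy_raw`` keeps the
    unclamped estimate.  ``detectable`` applies the assay's reporting
    threshold (>= counts as detectable).
    """

    sample_id: str
    lambda_x: float
    lambda_y: float
    conc_x: float
    conc_y: float
    pct_loy: float
    pct_loy_raw: float
    detectable: bool
    threshold_pct: float


def poisson_lambda(n_pos: int, n_total: int) -> float:
    """Mean template copies per droplet from positive-droplet counts."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValidationError(f"n_pos={n_pos} outside [0, {n_total}]")
    if n_pos == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive; channel saturated, lambda unbounded"
        )
    return -math.log(1.0 - n_pos / n_total)


def estimate_loy_pct(
    well: DropletWell, threshold_pct: float = DEFAULT_DETECTION_THRESHOLD_PCT
) -> DdpcrQuant:
    """Quantify %LOY for one two-channel well."""
    if well.n_pos_x < 1:
        raise ValidationError(
            f"well {well.sample_id!r}: zero positives on the X reference channel"
        )
    lam_x = poisson_lambda(well.n_pos_x, well.n_total)
    lam_y = poisson_lambda(well.n_pos_y, well.n_total)
    raw = 100.0 * (1.0 - lam_y / lam_x)
    pct = float(np.clip(raw, -100.0, 100.0))
    return DdpcrQuant(
        sample_id=well.sample_id,
        lambda_x=lam_x,
        lambda_y=lam_y,
        conc_x=lam_x / well.droplet_volume_ul,
        conc_y=lam_y / well.droplet_volume_ul,
        pct_loy=pct,
        pct_loy_raw=raw,
        detectable=pct >= threshold_pct,
        threshold_pct=threshold_pct,
    )


def quantify_wells(
    wells, threshold_pct: float = DEFAULT_DETECTION_THRESHOLD_PCT
) -> pd.DataFrame:
    """Quantify a list of wells into one row per sample."""
    return pd.DataFrame([estimate_loy_pct(w, threshold_pct).__dict__ for w in wells])


def apply_detection_threshold(
    values, threshold_pct: float = DEFAULT_DETECTION_THRESHOLD_PCT
) -> tuple[np.ndarray, int]:
    """Per-sample detectable flags (value >= threshold) and their count."""
    if threshold_pct < 0:
        raise ValidationError("detection threshold must be non-negative")
    values = np.asarray(values, dtype=float)
    flags = values >= threshold_pct
    return flags, int(flags.sum())


def cohort_detection_summary(
    table: pd.DataFrame | None = None,
    threshold_pct: float = DEFAULT_DETECTION_THRESHOLD_PCT,
) -> dict:
    """Detection counts for the bundled 20-patient cohort table.

    Reports, per diagnosis cohort and combined, the number of samples
    with detectable %LOY in tumor, uninvolved margin and blood, plus the
    largest detectable tumor %LOY.
    """
    if table is None:
        table = load_patient_loy_table()
    out: dict = {"threshold_pct": threshold_pct}
    for column in ("tumor_pct_loy", "um_pct_loy", "blood_pct_loy"):
        short = column.split("_")[0]
        _, out[f"{short}_detectable_all"] = apply_detection_threshold(
            table[column], threshold_pct
        )
        for diagnosis, sub in table.groupby("diagnosis"):
            _, n = apply_detection_threshold(sub[column], threshold_pct)
            out[f"{short}_detectable_{diagnosis}"] = n
    tumor_flags, _ = apply_detection_threshold(table["tumor_pct_loy"], threshold_pct)
    detectable_tumor = table["tumor_pct_loy"][tumor_flags]
    out["max_detectable_tumor_pct"] = float(detectable_tumor.max()) if len(detectable_tumor) else 0.0
    return out
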