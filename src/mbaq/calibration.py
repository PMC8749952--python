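"""Single-point median calibration against a generic internal standard.

The standard chimera digests into equimolar peptides whose XIC peak areas
cluster around a median; that median is the single-point calibrant.  The
standard's own molar amount is obtained by comparing its scrambled
reference peptides with the native peptides of a codigested reference
protein of known amount (e.g. 1 pmol BSA):

    amount_std   = amount_ref * median_pairs(area_scrambled / area_native)
    response     = amount_std / median(areas of the standard's NM peptides)
    NMA          = median(NM areas) / (amount_std * k_ref),
    k_ref        = median_pairs(area_native / amount_ref)

NMA (normalized median abundance) is unity exactly when the standard
peptides' median response matches the reference-derived response; deviation
from 1 measures calibrant bias.  Zero areas mean "not detected in this run"
and are excluded before every median.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .io_tables import ObservationTable, StandardSpec

logger = logging.getLogger("mbaq")

#: Below this many detected standard peptides the median's spread has not
#: yet reached its plateau and a warning is emitted.
MIN_STABLE_PEPTIDES = 30

#: Default near-median band: fraction of the median.
NEAR_MEDIAN_BAND = 0.20


@dataclass
class Calibration:
    """Per-run calibration of the internal standard."""

    run_id: str
    standard_amount: float          # mol
    median_area: float              # intensity units
    response_factor: float          # mol per intensity unit
    nma: float
    nm_fraction: float
    n_standard_peptides_detected: int
    per_pair_ratios: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.median_area <= 0:
            raise ValidationError("median area must be positive")
        if not 0.0 <= self.nm_fraction <= 1.0:
            raise ValidationError("near-median fraction must lie in [0, 1]")


def _pair_areas(
    table: ObservationTable, spec: StandardSpec, run: str
) -> tuple[list[float], list[float], list[tuple[str, str]]]:
    """Usable (native, scrambled) areas per reference pair; zeros skipped."""
    if not spec.calibration_capable:
        raise CalibrationError("standard specification has no reference pairs")
    natives = table.areas_for_peptides(run, [n for n, _ in spec.reference_pairs])
    scrambles = table.areas_for_peptides(run, [s for _, s in spec.reference_pairs])
    nat, scr, skipped = [], [], []
    for native, scrambled in spec.reference_pairs:
        a_n = natives.get(native, 0.0)
        a_s = scrambles.get(scrambled, 0.0)
        if a_n > 0 and a_s > 0:
            nat.append(a_n)
            scr.append(a_s)
        else:
            skipped.append((native, scrambled))
    if skipped:
        logger.warning("skipping %d reference pair(s) with missing areas", len(skipped))
    if not nat:
        raise CalibrationError(f"no usable native/scrambled reference pair in run {run!r}")
    return nat, scr, skipped


def estimate_standard_amount(
    table: ObservationTable, spec: StandardSpec, run: str
) -> tuple[float, list[float]]:
    """Molar amount of the standard from its scrambled/native reference pairs.

    amount = reference_amount x median over pairs of (scrambled / native)
    area ratio.  Pairs with either area 0 are skipped (and logged).
    """
    nat, scr, _ = _pair_areas(table, spec, run)
    ratios = [s / n for s, n in zip(scr, nat)]
    return spec.reference_amount * float(np.median(ratios)), ratios


def _standard_areas(table: ObservationTable, spec: StandardSpec, run: str) -> np.ndarray:
    areas = table.areas_for_peptides(run, spec.median_peptides)
    detected = np.array([a for a in areas.values() if a > 0], dtype=float)
    if detected.size == 0:
        raise CalibrationError(f"no standard peptide detected in run {run!r}")
    return detected


def median_calibrant(table: ObservationTable, spec: StandardSpec, run: str) -> "Calibration":
    """Full per-run calibration: amount, median area, response factor, QC."""
    amount, ratios = estimate_standard_amount(table, spec, run)
    detected = _standard_areas(table, spec, run)
    if detected.size < MIN_STABLE_PEPTIDES:
        logger.warning(
            "only %d standard peptides detected in run %s; the median spread "
            "plateaus above %d peptides",
            detected.size, run, MIN_STABLE_PEPTIDES,
        )
    median_area = float(np.median(detected))
    return Calibration(
        run_id=run,
        standard_amount=amount,
        median_area=median_area,
        response_factor=amount / median_area,
        nma=normalized_median_abundance(table, spec, run),
        nm_fraction=near_median_fraction(detected.tolist()),
        n_standard_peptides_detected=int(detected.size),
        per_pair_ratios=ratios,
    )


def normalized_median_abundance(table: ObservationTable, spec: StandardSpec, run: str) -> float:
    """NMA: median standard-peptide area over the reference-derived expectation."""
    amount, _ = estimate_standard_amount(table, spec, run)
    nat, _, _ = _pair_areas(table, spec, run)
    k_ref = float(np.median([a / spec.reference_amount for a in nat]))
    expected_area = amount * k_ref
    detected = _standard_areas(table, spec, run)
    return float(np.median(detected)) / expected_area


def near_median_fraction(areas: list[float], band: float = NEAR_MEDIAN_BAND) -> float:
    """Fraction of areas within ``band`` (relative) of their median."""
    arr = np.asarray([a for a in areas if a > 0], dtype=float)
    if arr.size == 0:
        raise ValidationError("near-median fraction needs at least one positive area")
    m = float(np.median(arr))
    return float(np.mean(np.abs(arr - m) / m <= band))


def calibrate_all_runs(
    table: ObservationTable, spec: StandardSpec, pooled: bool = False
) -> dict[str, Calibration]:
    """Calibrate every run; the default is strictly per-run.

    With ``pooled`` the runs are treated as technical replicates of one
    digest: the standard amount is the median over every (run, pair)
    ratio and the calibrant the median over every detected standard area,
    giving one shared response factor.
    """
    per_run = {run: median_calibrant(table, spec, run) for run in table.runs}
    if not pooled:
        return per_run
    all_ratios = [r for c in per_run.values() for r in c.per_pair_ratios]
    amount = spec.reference_amount * float(np.median(all_ratios))
    all_areas = np.concatenate(
        [_standard_areas(table, spec, run) for run in table.runs]
    )
    median_area = float(np.median(all_areas))
    pooled_factor = amount / median_area
    for c in per_run.values():
        c.standard_amount = amount
        c.median_area = median_area
        c.response_factor = pooled_factor
    return per_run


def write_calibration_report(calibrations: dict[str, Calibration], tsv_path, json_path=None) -> None:
    rows = [
        {
            "run": c.run_id,
            "standard_amount_fmol": c.standard_amount / 1e-15,
            "median_area": c.median_area,
            "response_factor_fmol_per_unit": c.response_factor / 1e-15,
            "nma": c.nma,
            "nm_fraction": c.nm_fraction,
            "n_detected": c.n_standard_peptides_detected,
        }
        for c in calibrations.values()
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({run: asdict(c) for run, c in calibrations.items()}, fh, indent=2)
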