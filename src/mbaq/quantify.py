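"""Protein quantification from calibrated peptide molar estimates.

Each detected peptide's molar estimate is its XIC area times the run's
response factor.  A protein's amount is the mean over a selected peptide
set: TopN (the N most abundant), Hi-3 (Top3), or BestN — the size-2 or
size-3 subset of the Top3 pool with the smallest coefficient of variation.
Proteins identified with a single peptide are excluded; proteins with two
peptides use that pair directly (qc_pass reflects its CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .calibration import Calibration
from .errors import ProteinLookupError, SinglePeptideError, ValidationError
from .io_tables import ObservationTable, StandardSpec

AVOGADRO = 6.02214076e23

#: QC threshold on the coefficient of variation of the selected peptide set (%).
CV_THRESHOLD = 20.0

#: Tolerance of the optional mean/median concordance filter.
MEAN_MEDIAN_TOL = 0.15


@dataclass
class ProteinQuant:
    """Per-protein, per-run molar quantification result."""

    protein_id: str
    run_id: str
    method: str                      # bestn | topn | hi3
    selected_peptides: list[str]
    amount: float                    # mol
    cv_percent: float
    n_peptides_available: int
    qc_pass: bool


def cv_percent(values: list[float]) -> float:
    """Coefficient of variation in %: sample (n-1) SD over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("CV needs at least two values")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValidationError("CV undefined for non-positive mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


def peptide_molar_estimates(
    table: ObservationTable, protein_id: str, run: str, response_factor: float
) -> dict[str, float]:
    """Molar estimate (area x response factor) per detected peptide."""
    view = table.run_view(run)
    rows = view[view["protein_id"] == protein_id]
    if rows.empty:
        raise ProteinLookupError(f"protein {protein_id!r} has no observations in run {run!r}")
    estimates = {
        seq: area * response_factor
        for seq, area in zip(rows["peptide_seq"], rows["xic_area"])
        if area > 0
    }
    if not estimates:
        raise ProteinLookupError(f"protein {protein_id!r} not detected in run {run!r}")
    return estimates


def select_topn(estimates: dict[str, float], n: int = 3) -> list[str]:
    """The n peptides with the largest estimates; ties broken by sequence."""
    if not estimates:
        raise ValidationError("no estimates to select from")
    ranked = sorted(estimates, key=lambda p: (-estimates[p], p))
    return ranked[:n]


def select_bestn(
    estimates: dict[str, float], cv_threshold: float = CV_THRESHOLD
) -> tuple[list[str], float, bool]:
    """Minimum-CV subset (size 2 or 3) of the Top3 pool.

    With exactly two peptides the pair is returned directly (its CV may
    exceed the threshold; qc_pass records that).  A single peptide raises
    :class:`SinglePeptideError` — such proteins are excluded upstream.
    """
    if len(estimates) < 2:
        raise SinglePeptideError("proteins identified with one peptide are excluded")
    pool = select_topn(estimates, n=3)
    if len(pool) == 2:
        cv = cv_percent([estimates[p] for p in pool])
        return pool, cv, cv < cv_threshold
    candidates = [list(c) for r in (2, 3) for c in combinations(sorted(pool), r)]
    best = min(candidates, key=lambda c: (cv_percent([estimates[p] for p in c]), tuple(c)))
    cv = cv_percent([estimates[p] for p in best])
    return best, cv, cv < cv_threshold


def mean_median_consistency(estimates: dict[str, float] | list[float], tol: float = MEAN_MEDIAN_TOL) -> bool:
    """True when the estimates' mean and median differ by less than ``tol``."""
    values = list(estimates.values()) if isinstance(estimates, dict) else list(estimates)
    if len(values) < 2:
        raise ValidationError("consistency check needs at least two estimates")
    arr = np.asarray(values, dtype=float)
    median = float(np.median(arr))
    return abs(float(arr.mean()) - median) / median < tol


def quantify_protein(
    estimates: dict[str, float],
    method: str = "bestn",
    cv_threshold: float = CV_THRESHOLD,
    protein_id: str = "",
    run_id: str = "",
) -> ProteinQuant:
    """Quantify one protein from its peptide molar estimates."""
    if method == "bestn":
        selected, cv, qc = select_bestn(estimates, cv_threshold)
    elif method in ("topn", "hi3"):
        if len(estimates) < 2:
            raise SinglePeptideError("proteins identified with one peptide are excluded")
        selected = select_topn(estimates, n=3)
        cv = cv_percent([estimates[p] for p in selected])
        qc = cv < cv_threshold
    else:
        raise ValidationError(f"unknown method {method!r}")
    amount = float(np.mean([estimates[p] for p in selected]))
    return ProteinQuant(
        protein_id=protein_id,
        run_id=run_id,
        method=method,
        selected_peptides=selected,
        amount=amount,
        cv_percent=cv,
        n_peptides_available=len(estimates),
        qc_pass=qc,
    )


def quantify_run(
    table: ObservationTable,
    spec: StandardSpec,
    calibration: Calibration,
    method: str = "bestn",
    cv_threshold: float = CV_THRESHOLD,
    mean_median_filter: bool = False,
    exclude_shared_peptides: bool = True,
) -> tuple[list[ProteinQuant], list[tuple[str, str]]]:
    """Quantify every analyte protein in one run.

    Returns (quantifications, excluded) where ``excluded`` lists
    (protein_id, reason) for proteins that could not be quantified.
    Peptides shared between proteins are flagged and dropped by default.
    """
    run = calibration.run_id
    view = table.run_view(run)
    analyte = view[~view["protein_id"].isin([spec.standard_protein_id, spec.reference_protein_id])]
    excluded: list[tuple[str, str]] = []
    if exclude_shared_peptides:
        owners = table.df.groupby("peptide_seq")["protein_id"].nunique()
        shared = set(owners[owners > 1].index)
        if shared:
            analyte = analyte[~analyte["peptide_seq"].isin(shared)]
    results: list[ProteinQuant] = []
    for protein_id in analyte["protein_id"].unique():
        try:
            estimates = peptide_molar_estimates(table, protein_id, run, calibration.response_factor)
        except ProteinLookupError:
            excluded.append((protein_id, "not detected"))
            continue
        if mean_median_filter and len(estimates) >= 2 and not mean_median_consistency(estimates):
            excluded.append((protein_id, "mean/median discordant"))
            continue
        try:
            results.append(
                quantify_protein(estimates, method, cv_threshold, protein_id, run)
            )
        except SinglePeptideError:
            excluded.append((protein_id, "single peptide"))
    return results, excluded


# ---------------------------------------------------------------------------
# comparison metrics


def percent_error(estimate: float, reference: float) -> float:
    """100 x |estimate - reference| / reference."""
    if reference <= 0:
        raise ValidationError("reference value must be positive")
    return 100.0 * abs(estimate - reference) / reference


def copies_per_cell(amount: float, n_cells: int) -> float:
    """Convert a molar amount into protein copies per cell."""
    if n_cells <= 0:
        raise ValidationError("cell count must be positive")
    return amount * AVOGADRO / n_cells


def dilution_concordance(
    quants_a: list[ProteinQuant],
    quants_b: list[ProteinQuant],
    expected_ratio: float,
) -> dict:
    """Per-protein amount ratios between two samples vs an expected ratio.

    Amounts are aggregated per protein by the median over runs before
    forming ratio = amount_a / amount_b.  Per-protein accuracy is
    100 x (1 - |ratio - expected| / expected); the summary reports the
    mean (and median) accuracy over shared proteins.
    """
    def per_protein(quants):
        df = pd.DataFrame([(q.protein_id, q.amount) for q in quants], columns=["protein", "amount"])
        return df.groupby("protein")["amount"].median()

    a, b = per_protein(quants_a), per_protein(quants_b)
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValidationError("no protein quantified in both samples")
    ratios = {p: float(a[p] / b[p]) for p in shared}
    accuracies = {
        p: 100.0 * (1.0 - abs(r - expected_ratio) / expected_ratio) for p, r in ratios.items()
    }
    missing = sorted(set(a.index) ^ set(b.index))
    return {
        "ratios": ratios,
        "accuracies": accuracies,
        "mean_ratio": float(np.mean(list(ratios.values()))),
        "mean_accuracy": float(np.mean(list(accuracies.values()))),
        "median_accuracy": float(np.median(list(accuracies.values()))),
        "missing_proteins": missing,
    }


def write_protein_table(
    quants: list[ProteinQuant], path, n_cells: int | None = None
) -> None:
    rows = []
    for q in quants:
        row = {
            "protein": q.protein_id,
            "run": q.run_id,
            "method": q.method,
            "n_available": q.n_peptides_available,
            "selected_peptides": ";".join(q.selected_peptides),
            "amount_fmol": q.amount / 1e-15,
            "cv_percent": q.cv_percent,
            "qc_pass": q.qc_pass,
        }
        if n_cells is not None:
            row["copies_per_cell"] = copies_per_cell(q.amount, n_cells)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
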