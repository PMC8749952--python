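"""Peptide quantification tables, standard specifications and FASTA I/O.

The quantification input is the long-format CSV produced by LC-MS label-free
alignment software (one row per run x protein x peptide with the raw XIC peak
area); the column names of the dialect are user-configurable through a
``column_map``.  The internal standard (its peptide list, the native/scrambled
reference-peptide pairs and the molar amount of the codigested reference
protein) is described by a small key-value YAML file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("mbaq")

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default column dialect for a long-format peptide measurement export.
DEFAULT_COLUMNS: dict[str, str] = {
    "run": "run",
    "protein": "protein",
    "peptide": "peptide",
    "area": "area",
    "rt": "rt",
}

_MOD_ANNOTATION = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def clean_peptide_seq(raw: str) -> str:
    """Normalize an exported peptide string to a bare uppercase sequence.

    Modification annotations in brackets or parentheses (e.g. ``M(ox)`` or
    ``C[+57.02]``) are stripped; comparison is case-insensitive.
    """
    seq = _MOD_ANNOTATION.sub("", str(raw)).strip().upper()
    if not seq:
        raise ValidationError(f"empty peptide sequence after cleaning: {raw!r}")
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        raise ValidationError(
            f"peptide {raw!r} contains non-canonical residues {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class PeptideObservation:
    """One peptide's XIC peak area in one LC-MS run."""

    run_id: str
    protein_id: str
    peptide_seq: str
    xic_area: float
    rt_min: float | None = None
    is_standard: bool = False

    def __post_init__(self):
        if self.xic_area < 0:
            raise ValidationError(
                f"negative XIC area {self.xic_area} for {self.peptide_seq}"
            )
        object.__setattr__(self, "peptide_seq", clean_peptide_seq(self.peptide_seq))


_TABLE_COLUMNS = ["run_id", "protein_id", "peptide_seq", "xic_area", "rt_min", "is_standard"]


@dataclass
class ObservationTable:
    """Container for peptide observations across a set of runs.

    Backed by a :class:`pandas.DataFrame` with one row per
    (run, protein, peptide); the key is unique within a table.
    """

    df: pd.DataFrame
    runs: list[str] = field(default_factory=list)

    @classmethod
    def from_observations(cls, observations: list[PeptideObservation]) -> "ObservationTable":
        if not observations:
            raise ValidationError("an observation table may not be empty")
        df = pd.DataFrame([o.__dict__ for o in observations], columns=_TABLE_COLUMNS)
        return cls._finalize(df)

    @classmethod
    def _finalize(cls, df: pd.DataFrame) -> "ObservationTable":
        key = ["run_id", "protein_id", "peptide_seq"]
        dups = df.duplicated(key, keep=False)
        if dups.any():
            n = int(dups.sum())
            logger.warning(
                "aggregating %d duplicate (run, protein, peptide) rows by summing areas", n
            )
            df = (
                df.groupby(key, as_index=False, sort=False)
                .agg(
                    xic_area=("xic_area", "sum"),
                    rt_min=("rt_min", "first"),
                    is_standard=("is_standard", "any"),
                )
            )
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
        runs = sorted(df["run_id"].unique().tolist())
        return cls(df=df[_TABLE_COLUMNS], runs=runs)

    def __len__(self) -> int:
        return len(self.df)

    def run_view(self, run_id: str) -> pd.DataFrame:
        if run_id not in self.runs:
            raise ValidationError(f"unknown run {run_id!r}; runs are {self.runs}")
        return self.df[self.df["run_id"] == run_id]

    def areas_for_peptides(self, run_id: str, peptides: list[str]) -> dict[str, float]:
        """Map peptide -> XIC area in one run, restricted to ``peptides``.

        Peptides absent from the run are simply missing from the map.
        """
        view = self.run_view(run_id)
        wanted = view[view["peptide_seq"].isin(peptides)]
        return dict(zip(wanted["peptide_seq"], wanted["xic_area"]))

    def scaled(self, factor: float) -> "ObservationTable":
        """Return a copy with every XIC area multiplied by ``factor``."""
        df = self.df.copy()
        df["xic_area"] = df["xic_area"] * factor
        return ObservationTable(df=df, runs=list(self.runs))


@dataclass
class StandardSpec:
    """The internal standard: peptides, reference pairs, reference amount.

    ``reference_pairs`` are (native, scrambled) peptide sequences: the native
    sequence belongs to the codigested reference protein (e.g. BSA), the
    scrambled counterpart is part of the standard chimera.  ``reference_amount``
    is the molar amount (mol) of codigested reference protein.
    """

    standard_peptides: list[str]
    reference_pairs: list[tuple[str, str]]
    reference_amount: float
    standard_protein_id: str = "STANDARD"
    reference_protein_id: str = "REFERENCE"

    def __post_init__(self):
        self.standard_peptides = [clean_peptide_seq(p) for p in self.standard_peptides]
        self.reference_pairs = [
            (clean_peptide_seq(n), clean_peptide_seq(s)) for n, s in self.reference_pairs
        ]
        std = set(self.standard_peptides)
        for native, scrambled in self.reference_pairs:
            if scrambled not in std:
                raise ValidationError(
                    f"scrambled reference peptide {scrambled} is not part of the standard"
                )
        if self.reference_amount <= 0:
            raise ValidationError("reference amount must be positive")

    @property
    def calibration_capable(self) -> bool:
        return len(self.reference_pairs) > 0

    @property
    def median_peptides(self) -> list[str]:
        """Standard peptides that define the median calibrant.

        The scrambled reference peptides determine the standard's molar
        amount; the remaining (near-median) peptides define the median.
        """
        scrambled = {s for _, s in self.reference_pairs}
        return [p for p in self.standard_peptides if p not in scrambled]


# ---------------------------------------------------------------------------
# readers / writers


def read_peptide_table(
    path, column_map: dict[str, str] | None = None
) -> ObservationTable:
    """Read a long-format peptide quantification CSV.

    ``column_map`` maps the logical names ``run``, ``protein``, ``peptide``,
    ``area`` (and optionally ``rt``) to the header names of the export
    dialect; :data:`DEFAULT_COLUMNS` is used where not overridden.
    Duplicate (run, protein, peptide) rows (charge states, modified forms)
    are summed with a logged warning; zero areas are retained.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)
    for logical in ("run", "protein", "peptide", "area"):
        if cols[logical] not in df.columns:
            raise ConfigurationError(
                f"column {cols[logical]!r} (mapped from {logical!r}) "
                f"not found in {path}; available: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "run_id": df[cols["run"]].astype(str),
            "protein_id": df[cols["protein"]].astype(str),
            "peptide_seq": df[cols["peptide"]].map(clean_peptide_seq),
            "xic_area": pd.to_numeric(df[cols["area"]], errors="raise"),
        }
    )
    out["rt_min"] = (
        pd.to_numeric(df[cols["rt"]], errors="raise") if cols["rt"] in df.columns else None
    )
    out["is_standard"] = False
    neg = out.index[out["xic_area"] < 0]
    if len(neg):
        raise ValidationError(f"negative XIC area at row {int(neg[0]) + 2} of {path}")
    if out.empty:
        raise ValidationError(f"{path} contains no observations")
    return ObservationTable._finalize(out)


def write_peptide_table(table: ObservationTable, path, column_map: dict[str, str] | None = None) -> None:
    """Write a table back to CSV in the (possibly remapped) input dialect."""
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    out = pd.DataFrame(
        {
            cols["run"]: table.df["run_id"],
            cols["protein"]: table.df["protein_id"],
            cols["peptide"]: table.df["peptide_seq"],
            cols["area"]: table.df["xic_area"],
            cols["rt"]: table.df["rt_min"],
        }
    )
    out.to_csv(path, index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (header, uppercased sequence), '*' stripped."""
    try:
        records = [
            (rec.description, str(rec.seq).upper().replace("*", ""))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:
        raise ValidationError(f"{path} is not well-formed FASTA: {exc}") from exc
    if not records:
        raise ValidationError(f"{path} contains no FASTA records")
    return records


def read_standard_spec(path) -> StandardSpec:
    """Read a standard specification from a key-value YAML file.

    Expected keys: ``standard_peptides`` (list), ``reference_pairs``
    (list of [native, scrambled]), ``reference_amount_fmol`` (number),
    optional ``standard_protein_id`` / ``reference_protein_id``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} is not a key-value standard specification")
    try:
        peptides = list(raw["standard_peptides"])
        pairs = [tuple(p) for p in raw.get("reference_pairs", [])]
        amount_fmol = float(raw["reference_amount_fmol"])
    except KeyError as exc:
        raise ConfigurationError(f"standard spec {path} is missing key {exc}") from exc
    spec = StandardSpec(
        standard_peptides=peptides,
        reference_pairs=pairs,
        reference_amount=amount_fmol * 1e-15,
        standard_protein_id=str(raw.get("standard_protein_id", "STANDARD")),
        reference_protein_id=str(raw.get("reference_protein_id", "REFERENCE")),
    )
    if not spec.calibration_capable:
        logger.warning(
            "standard spec %s has no reference pairs: calibration-incapable", path
        )
    return spec


def write_standard_spec(spec: StandardSpec, path) -> None:
    payload = {
        "standard_peptides": list(spec.standard_peptides),
        "reference_pairs": [list(p) for p in spec.reference_pairs],
        "reference_amount_fmol": spec.reference_amount / 1e-15,
        "standard_protein_id": spec.standard_protein_id,
        "reference_protein_id": spec.reference_protein_id,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
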