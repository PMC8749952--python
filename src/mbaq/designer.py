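"""Design computations for a generic internal-standard chimera.

The standard is a concatenation of artificial tryptic peptides derived from
real proteotypic peptides by *scrambling*: small sequence edits that destroy
identity to any natural sequence while preserving length, net charge, the
C-terminal K/R, hydropathy and (approximately) retention behavior.  Allowed
edits are a swap of two non-terminal residues and conservative substitutions
(S<->T, D<->E, N<->Q, F<->Y, and aliphatic residues of similar hydropathy);
at least one substitution must shift the monoisotopic mass so the scrambled
peptide is distinguishable from its source by MS.

Plain sequence reversal (keeping the C-terminal K/R) is also provided, but
reversed peptides ionize poorly relative to their sources and are kept only
for comparison.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from pyteomics import mass as _ptmass

from .errors import ConfigurationError, DesignError, ValidationError
from .io_tables import CANONICAL_RESIDUES, clean_peptide_seq, read_fasta

#: Unordered conservative substitution pairs outside the aliphatic group.
_POLAR_SUBSTITUTIONS = {frozenset(p) for p in ("ST", "DE", "NQ", "FY")}

_ALIPHATIC = "GAVLI"
#: Aliphatic substitutions: similar hydropathy only (|dKD| <= 2.5), so
#: e.g. V<->L and V<->I are allowed but G<->I is not.
_ALIPHATIC_KD_LIMIT = 2.5
_ALIPHATIC_SUBSTITUTIONS = {
    frozenset((a, b))
    for i, a in enumerate(_ALIPHATIC)
    for b in _ALIPHATIC[i + 1 :]
    if abs(KYTE_DOOLITTLE[a] - KYTE_DOOLITTLE[b]) <= _ALIPHATIC_KD_LIMIT
}

ALLOWED_SUBSTITUTIONS = _POLAR_SUBSTITUTIONS | _ALIPHATIC_SUBSTITUTIONS

MAX_SWAPS = 1
MAX_SUBSTITUTIONS = 2

#: Scrambles shifting mean hydropathy by more than this trigger a warning
#: (retention time is not predicted; hydropathy is the proxy).
HYDROPATHY_WARN = 0.5


def substitution_allowed(a: str, b: str) -> bool:
    return a != b and frozenset((a, b)) in ALLOWED_SUBSTITUTIONS


def mono_mass(sequence: str) -> float:
    """Monoisotopic peptide mass (Da): residue masses plus water."""
    seq = clean_peptide_seq(sequence)
    return float(_ptmass.calculate_mass(sequence=seq))


def hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy index of the sequence."""
    seq = clean_peptide_seq(sequence)
    return sum(KYTE_DOOLITTLE[r] for r in seq) / len(seq)


# ---------------------------------------------------------------------------
# digestion and proteotypic filtering


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def digest_trypsin(sequence: str, max_missed: int = 0) -> list[DigestPeptide]:
    """In-silico tryptic digest: cleave after K/R except before P."""
    seq = clean_peptide_seq(sequence)
    cut_after = [
        i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    fragments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    peptides = []
    for i in range(len(fragments)):
        for missed in range(min(max_missed, len(fragments) - 1 - i) + 1):
            start = fragments[i][0]
            end = fragments[i + missed][1]
            peptides.append(
                DigestPeptide(
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                )
            )
    return sorted(peptides, key=lambda p: (p.start, p.end))


def proteotypic_filter(
    peptides, min_len: int = 7, max_len: int = 25
) -> tuple[list[str], dict[str, list[str]]]:
    """Keep chimera-suitable peptides; report rejection reasons per peptide.

    Rules: fully tryptic (C-terminal K/R) with no missed cleavage, no
    cysteine or methionine anywhere, N-terminal residue not D/E, length
    within [min_len, max_len].
    """
    kept: list[str] = []
    reasons: dict[str, list[str]] = {}
    for pep in peptides:
        if isinstance(pep, DigestPeptide):
            seq, missed = pep.sequence, pep.missed_cleavages
        else:
            seq, missed = clean_peptide_seq(pep), 0
        why = []
        if missed > 0:
            why.append("missed_cleavage")
        if not min_len <= len(seq) <= max_len:
            why.append("length")
        if seq[-1] not in "KR":
            why.append("non_tryptic_terminus")
        if "C" in seq or "M" in seq:
            why.append("cys_or_met")
        if seq[0] in "DE":
            why.append("nterm_acidic")
        if why:
            reasons[seq] = why
        else:
            kept.append(seq)
    return kept, reasons


def reverse_except_cterm(sequence: str) -> str:
    """Reverse the sequence keeping the C-terminal K/R in place."""
    seq = clean_peptide_seq(sequence)
    if len(seq) < 2 or seq[-1] not in "KR":
        raise ValidationError(f"{seq} lacks a C-terminal K/R tryptic terminus")
    return seq[:-1][::-1] + seq[-1]


# ---------------------------------------------------------------------------
# scrambling


@dataclass
class ScrambleResult:
    """A designed (or validated) scrambled peptide and its edit events.

    Events use 1-based positions: ``("swap", i, j)`` exchanges residues i
    and j; ``("substitute", i, old, new)`` replaces the residue at i.
    """

    source_seq: str
    product_seq: str
    events: list[tuple] = field(default_factory=list)
    mono_mass_delta: float = 0.0
    hydropathy_delta: float = 0.0
    unique_vs_db: bool | None = None   # None: untested
    valid: bool = False
    violations: list[str] = field(default_factory=list)

    @property
    def n_swaps(self) -> int:
        return sum(1 for e in self.events if e[0] == "swap")

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.events if e[0] == "substitute")


def _finish_result(source: str, product: str, events: list[tuple], violations: list[str]) -> ScrambleResult:
    return ScrambleResult(
        source_seq=source,
        product_seq=product,
        events=events,
        mono_mass_delta=mono_mass(product) - mono_mass(source) if product else 0.0,
        hydropathy_delta=hydropathy(product) - hydropathy(source) if product else 0.0,
        valid=not violations,
        violations=violations,
    )


def validate_scramble(native: str, candidate: str) -> ScrambleResult:
    """Check a candidate against the scrambling rules; infer minimal events.

    The minimal event set is inferred from the changed positions: mutually
    exchanged position pairs become swaps, the rest substitutions.  Valid
    means: at most one swap and at most two substitutions, every
    substitution conservative, C-terminus unchanged, product differs from
    the source, and the total monoisotopic mass shift is nonzero.
    """
    native = clean_peptide_seq(native)
    candidate = clean_peptide_seq(candidate)
    if len(native) != len(candidate):
        raise ValidationError("native and candidate sequences differ in length")
    changed = [i for i in range(len(native)) if native[i] != candidate[i]]
    events: list[tuple] = []
    used: set[int] = set()
    for i in changed:
        if i in used:
            continue
        for j in changed:
            if j <= i or j in used:
                continue
            if native[i] == candidate[j] and native[j] == candidate[i]:
                events.append(("swap", i + 1, j + 1))
                used.update((i, j))
                break
    subs = [i for i in changed if i not in used]
    events.extend(("substitute", i + 1, native[i], candidate[i]) for i in subs)
    events.sort(key=lambda e: e[1])

    violations = []
    if not changed:
        violations.append("product_equals_source")
    if changed and changed[-1] == len(native) - 1:
        violations.append("c_terminus_changed")
    n_swaps = sum(1 for e in events if e[0] == "swap")
    if n_swaps > MAX_SWAPS:
        violations.append("too_many_swaps")
    if len(subs) > MAX_SUBSTITUTIONS:
        violations.append("too_many_substitutions")
    for i in subs:
        if not substitution_allowed(native[i], candidate[i]):
            violations.append(f"disallowed_substitution:{native[i]}>{candidate[i]}")
    result = _finish_result(native, candidate, events, violations)
    if changed and abs(result.mono_mass_delta) < 1e-6:
        result.violations.append("zero_mass_delta")
        result.valid = False
    return result


def _substitution_options(seq: str) -> list[tuple[int, str]]:
    """(position, replacement) options with a nonzero mass shift; C-term kept."""
    opts = []
    for i, res in enumerate(seq[:-1]):
        for other in sorted(CANONICAL_RESIDUES):
            if substitution_allowed(res, other) and abs(
                _ptmass.std_aa_mass[other] - _ptmass.std_aa_mass[res]
            ) > 1e-6:
                opts.append((i, other))
    return opts


def scramble_peptide(sequence: str, seed: int = 0) -> ScrambleResult:
    """Design a scrambled counterpart: one swap plus one mass-shifting
    conservative substitution, the substitution preferring the middle third
    of the sequence.  Deterministic for a given seed."""
    seq = clean_peptide_seq(sequence)
    if len(seq) < 4 or seq[-1] not in "KR":
        raise ValidationError(f"{seq} is not a tryptic proteotypic peptide")
    rng = random.Random(seed)

    swap_pairs = [
        (i, j)
        for i in range(len(seq) - 1)
        for j in range(i + 1, len(seq) - 1)
        if seq[i] != seq[j]
    ]
    sub_options = _substitution_options(seq)
    violations = []
    if not swap_pairs:
        violations.append("no_swap_possible")
    if not sub_options:
        violations.append("no_substitution_possible")
    if violations:
        raise DesignError(f"cannot scramble {seq}", violations)

    lo, hi = len(seq) // 3, len(seq) - len(seq) // 3
    rng.shuffle(swap_pairs)

    def sub_rank(opt):
        # middle-third positions first, then minimal hydropathy disturbance
        pos, new = opt
        in_middle = 0 if lo <= pos < hi else 1
        return (in_middle, abs(KYTE_DOOLITTLE[new] - KYTE_DOOLITTLE[seq[pos]]), rng.random())

    ordered_subs = sorted(sub_options, key=sub_rank)
    for i, j in swap_pairs:
        for p, new in ordered_subs:
            if p in (i, j):
                continue
            prod = list(seq)
            prod[i], prod[j] = prod[j], prod[i]
            old = prod[p]
            prod[p] = new
            product = "".join(prod)
            events = sorted(
                [("swap", i + 1, j + 1), ("substitute", p + 1, old, new)],
                key=lambda e: e[1],
            )
            if product != seq:
                return _finish_result(seq, product, events, [])
    raise DesignError(f"cannot scramble {seq}", ["no_valid_combination"])


# ---------------------------------------------------------------------------
# uniqueness against proteome databases


def uniqueness_check(
    candidate: str, proteome_fastas: list, max_missed: int = 1
) -> tuple[bool, list[tuple[str, str]]]:
    """Is the candidate absent from every supplied proteome?

    Reports (unique, matches) where matches are (protein header, kind);
    kind is "substring" for a verbatim occurrence inside a protein and
    "tryptic_peptide" when the candidate equals one of its tryptic
    peptides with up to ``max_missed`` missed cleavages.
    """
    if not proteome_fastas:
        raise ConfigurationError("at least one proteome FASTA is required")
    cand = clean_peptide_seq(candidate)
    matches: list[tuple[str, str]] = []
    for db in proteome_fastas:
        records = read_fasta(db) if not isinstance(db, list) else db
        for header, seq in records:
            if cand in seq:
                kind = "substring"
                if any(
                    p.sequence == cand for p in digest_trypsin(seq, max_missed=max_missed)
                ):
                    kind = "tryptic_peptide"
                matches.append((header, kind))
    return (len(matches) == 0), matches


# ---------------------------------------------------------------------------
# whole-standard design


def design_standard(
    peptides: list[str], seed: int = 0, proteome_fastas: list | None = None
) -> list[ScrambleResult]:
    """Scramble a list of source peptides into standard candidates.

    Each peptide gets its own seed derived from ``seed`` so the design is
    order-independent and reproducible; uniqueness is checked when
    databases are given.  Peptides that cannot be scrambled are returned
    as invalid results carrying their violations.
    """
    results = []
    for idx, pep in enumerate(peptides):
        try:
            res = scramble_peptide(pep, seed=seed * 100003 + idx)
        except DesignError as exc:
            res = ScrambleResult(
                source_seq=clean_peptide_seq(pep),
                product_seq="",
                valid=False,
                violations=exc.violations,
            )
        if res.valid and abs(res.hydropathy_delta) > HYDROPATHY_WARN:
            import logging
            logging.getLogger("mbaq").warning(
                "scramble %s -> %s shifts mean hydropathy by %.2f; retention "
                "behavior may differ", res.source_seq, res.product_seq,
                res.hydropathy_delta,
            )
        if res.valid and proteome_fastas:
            res.unique_vs_db, _ = uniqueness_check(res.product_seq, proteome_fastas)
        results.append(res)
    return results


def write_design_report(results: list[ScrambleResult], path) -> None:
    import pandas as pd

    rows = [
        {
            "source": r.source_seq,
            "product": r.product_seq,
            "events": ";".join("".join(map(str, e)) for e in r.events),
            "mono_mass_delta": r.mono_mass_delta,
            "hydropathy_delta": r.hydropathy_delta,
            "unique_vs_db": "untested" if r.unique_vs_db is None else r.unique_vs_db,
            "valid": r.valid,
            "violations": ";".join(r.violations),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_chimera_fasta(results: list[ScrambleResult], path, name: str = "chimera") -> None:
    """Write the concatenated scrambled peptides as one FASTA record."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise DesignError("no valid scrambled peptide to assemble")
    annotation = " ".join(
        f"{r.source_seq}>{r.product_seq}" for r in valid
    )
    with open(path, "w") as fh:
        fh.write(f">{name} {annotation}\n")
        seq = "".join(r.product_seq for r in valid)
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
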