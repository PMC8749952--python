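import pandas as pd
import pytest

from mbaq.io_tables import ObservationTable, StandardSpec


def make_table(rows):
    """Build an ObservationTable from (run, protein, peptide, area) tuples."""
    df = pd.DataFrame(rows, columns=["run_id", "protein_id", "peptide_seq", "xic_area"])
    df["rt_min"] = None
    df["is_standard"] = False
    return ObservationTable._finalize(
        df[["run_id", "protein_id", "peptide_seq", "xic_area", "rt_min", "is_standard"]]
    )


@pytest.fixture
def toy_spec():
    """Standard with 3 near-median peptides and one reference pair (1 pmol)."""
    return StandardSpec(
        standard_peptides=["AAGLLK", "TTSSPK", "VVNNQK", "NATIMEK"],
        reference_pairs=[("NATIVEK", "NATIMEK")],
        reference_amount=1e-12,
        standard_protein_id="STD",
        reference_protein_id="REF",
    )


def std_rows(run, nm_areas, scr_area, nat_area):
    """Observation rows matching toy_spec's layout."""
    nm = ["AAGLLK", "TTSSPK", "VVNNQK"]
    rows = [(run, "STD", p, a) for p, a in zip(nm, nm_areas)]
    rows.append((run, "STD", "NATIMEK", scr_area))
    rows.append((run, "REF", "NATIVEK", nat_area))
    return rows
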