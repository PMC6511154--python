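import io
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import svhotspot as sv


@pytest.fixture(scope="session")
def toy_table() -> pd.DataFrame:
    """A small hand-written ICGC-style breakpoint table."""
    rows = [
        # donor, project, chr_from, bkpt, range, chr_to, bkpt, range, type
        ("DO1", "BLOOD", "1", 100, "0", "2", 200, "2", "deletion"),
        ("DO1", "BLOOD", "chr1", 5000, "", "1", 7000, "5", "inversion"),
        ("DO2", "BLOOD", "2", 300, "15", "2", 400, "0", "deletion"),
        ("DO2", "BLOOD", "1", 900, "3", "Y", 100, "0", "interchromosomal"),
        ("DO3", "BREAST", "2", 1200, "10", "1", 2500, "10", "intrachromosomal"),
    ]
    cols = ["icgc_donor_id", "project_code", "chr_from", "chr_from_bkpt",
            "chr_from_range", "chr_to", "chr_to_bkpt", "chr_to_range",
            "variant_type"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def toy_table_file(toy_table, tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("ingest") / "breakpoints.tsv"
    toy_table.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def small_windows() -> sv.GenomicWindows:
    return sv.make_windows({"1": 25_000, "2": 10_000}, 10_000)


@pytest.fixture(scope="session")
def fixture_bundle():
    """One shared end-to-end synthetic input set (session-scoped for speed)."""
    return sv.end_to_end_fixture(sv.SimulationConfig(seed=11))


def table_to_records(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Round-trip a generated table through the TSV parser."""
    return sv.read_breakpoint_table(
        io.StringIO(table.to_csv(sep="\t", index=False)), **kwargs)
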