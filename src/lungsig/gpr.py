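"""Reading and writing GenePix-style .gpr spot tables.

The scanner software exports one tab-separated .gpr file per array: an ATF
header block (format line, record/field counts, quoted key=value records)
followed by a spot table whose columns include the local-background-corrected
median fluorescence.  Only the columns the analysis needs are modelled:
spot geometry, Name/ID, Flags and the intensity columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SPOT_COLUMNS

#: Background-corrected median intensity, as exported by GenePix.
CORRECTED_COLUMN = "F635 Median - B635"
FOREGROUND_COLUMN = "F635 Median"
BACKGROUND_COLUMN = "B635 Median"

#: Synthetic slides place 400 spots per block row purely for plausible geometry.
_BLOCK_SIZE = 400


class GprFormatError(ValueError):
    """Raised when a .gpr file lacks a required column or contains no spots."""


def _spot_name(feature_id: str, control_type: str) -> str:
    if control_type == "positive":
        return "E. coli lysate"
    if control_type == "negative":
        return "Buffer"
    return feature_id


def write_gpr(
    spots: pd.DataFrame, path: str | Path, array_id: str, background: float = 50.0
) -> Path:
    """Write one array's spots as a .gpr-dialect file.

    The corrected-intensity column carries the spot intensity verbatim (full
    float precision, so a read round-trips exactly); the foreground column is
    intensity + a flat background for readers that must subtract themselves.
    """
    path = Path(path)
    idx = spots["spot_id"].to_numpy()
    table = pd.DataFrame(
        {
            "Block": (idx - 1) // _BLOCK_SIZE + 1,
            "Column": (idx - 1) % _BLOCK_SIZE + 1,
            "Row": np.ones(len(spots), dtype=int),
            "Name": [
                _spot_name(f, c)
                for f, c in zip(spots["feature_id"], spots["control_type"])
            ],
            "ID": spots["feature_id"].to_numpy(),
            "Flags": np.where(spots["flag"].to_numpy(), -100, 0),
            FOREGROUND_COLUMN: spots["intensity"].to_numpy() + background,
            BACKGROUND_COLUMN: np.full(len(spots), background),
            CORRECTED_COLUMN: spots["intensity"].to_numpy(),
        }
    )
    records = [
        '"Type=GenePix Results 3"',
        f'"ArrayID={array_id}"',
        '"Wavelengths=635"',
        '"Settings=synthetic"',
    ]
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(records)}\t{table.shape[1]}\n")
        for rec in records:
            fh.write(rec + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def write_gpr_fixtures(
    spot_table: pd.DataFrame, directory: str | Path
) -> list[Path]:
    """Write one .gpr file per array of a long spot table; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for array_id, spots in spot_table.groupby("array_id", sort=True):
        paths.append(write_gpr(spots, directory / f"{array_id}.gpr", str(array_id)))
    return paths


def _parse_header(lines: list[str]) -> tuple[dict[str, str], int]:
    """Parse the ATF header; returns (records, index of the column-header line)."""
    if not lines or not lines[0].startswith("ATF"):
        raise GprFormatError("not an ATF/GPR file (missing ATF signature line)")
    try:
        n_records = int(lines[1].split("\t")[0])
    except (IndexError, ValueError) as exc:
        raise GprFormatError("malformed ATF count line") from exc
    records = {}
    for line in lines[2 : 2 + n_records]:
        body = line.strip().strip('"')
        key, _, value = body.partition("=")
        records[key] = value
    return records, 2 + n_records


def read_gpr(path: str | Path, array_id: str | None = None) -> pd.DataFrame:
    """Read a .gpr file into the long spot-table layout.

    Intensity is taken from the background-corrected median column when
    present, otherwise computed as foreground median - background median.
    Negative GenePix flag codes map to flagged (bad) spots.
    """
    path = Path(path)
    with open(path) as fh:
        head = [next(fh) for _ in range(2)]
        head += [next(fh) for _ in range(int(head[1].split("\t")[0]))]
        records, _ = _parse_header(head)
        table = pd.read_csv(fh, sep="\t")
    if table.empty:
        raise GprFormatError(f"{path.name}: spot table is empty")
    for required in ("ID", "Flags"):
        if required not in table.columns:
            raise GprFormatError(f"{path.name}: missing required column {required!r}")
    if CORRECTED_COLUMN in table.columns:
        intensity = table[CORRECTED_COLUMN].to_numpy(float)
    elif FOREGROUND_COLUMN in table.columns and BACKGROUND_COLUMN in table.columns:
        intensity = table[FOREGROUND_COLUMN].to_numpy(float) - table[
            BACKGROUND_COLUMN
        ].to_numpy(float)
    else:
        raise GprFormatError(
            f"{path.name}: no intensity column (need {CORRECTED_COLUMN!r} or "
            f"{FOREGROUND_COLUMN!r} + {BACKGROUND_COLUMN!r})"
        )
    if array_id is None:
        array_id = records.get("ArrayID", path.stem)
    ids = table["ID"].astype(str)
    control_type = np.where(
        ids.str.startswith("POS_"),
        "positive",
        np.where(ids == "NEG", "negative", "none"),
    )
    control_conc = np.where(
        ids.str.startswith("POS_"),
        ids.str.replace("POS_", "", regex=False),
        "nan",
    ).astype(float)
    out = pd.DataFrame(
        {
            "array_id": array_id,
            "spot_id": np.arange(1, len(table) + 1),
            "feature_id": ids.to_numpy(),
            "intensity": intensity,
            "flag": table["Flags"].to_numpy(float) < 0,
            "control_type": control_type,
            "control_conc": control_conc,
        }
    )
    return out[SPOT_COLUMNS]


def read_gpr_directory(directory: str | Path) -> pd.DataFrame:
    """Read every .gpr file in a directory into one long spot table."""
    paths = sorted(Path(directory).glob("*.gpr"))
    if not paths:
        raise GprFormatError(f"no .gpr files under {directory}")
    return pd.concat([read_gpr(p) for p in paths], ignore_index=True)
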