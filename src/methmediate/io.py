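"""Plain-text readers/writers for the pipeline's tabular formats.

Beta matrices travel as TSV (rows = probe ids, columns = sample ids, empty
cell = missing); sample sheets as CSV with the documented column dictionary;
reference profiles as TSV (rows = probes, columns = cell types); truth and
filter reports as JSON. Reads validate ranges and identifiers and report the
offending row/column on failure; write-then-read round trips are lossless
including the missingness mask.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .containers import (
    FilterReport,
    MethylationMatrix,
    ReferenceProfiles,
    ValidationError,
    validate_sample_sheet,
)


class ParseError(ValueError):
    """A file failed validation; the message carries row/column context."""


def write_beta_matrix(matrix: MethylationMatrix, path: str, annotations_path: str | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="")
    if annotations_path is not None:
        matrix.annotations.to_csv(annotations_path, sep="\t", index_label="probe_id")


def read_beta_matrix(path: str, annotations_path: str | None = None) -> MethylationMatrix:
    """Parse a beta-matrix TSV; empty cells become missing entries."""
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty input file")
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate probe ids {dup[:5]}")
    if pd.Index(values.columns).duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    arr = values.to_numpy(dtype=float)
    bad = np.isfinite(arr) & ((arr <= 0.0) | (arr >= 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: beta value {arr[i, j]!r} out of (0,1) at probe "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    annotations = None
    if annotations_path is not None:
        annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    try:
        return MethylationMatrix(values, annotations)
    except ValidationError as exc:  # pragma: no cover - re-raise with file context
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: pd.DataFrame, path: str) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Parse and validate the per-sample covariate CSV.

    Checks the required columns, the smoking-status levels, the rule that
    years_since_quit is present exactly for former smokers, and pair
    integrity (each pair id appears on exactly one case and one control).
    """
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty input file")
    sheet = pd.read_csv(path)
    try:
        return validate_sample_sheet(sheet)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_reference_profiles(reference: ReferenceProfiles, path: str) -> None:
    reference.profiles.to_csv(path, sep="\t", index_label="probe_id")


def read_reference_profiles(path: str) -> ReferenceProfiles:
    profiles = pd.read_csv(path, sep="\t", index_col=0)
    return ReferenceProfiles(profiles)


def write_truth(truth, path: str) -> None:
    """Persist the generator ground truth as JSON (cell proportions included)."""
    payload = {
        "seed": truth.seed,
        "mediator_probes": truth.mediator_probes,
        "outcome_coefficients": truth.outcome_coefficients,
        "natural_effects": truth.natural_effects,
        "probe_smoking_factor": truth.probe_smoking_factor.to_dict(),
        "cell_proportions": {
            "index": truth.cell_proportions.index.tolist(),
            "columns": truth.cell_proportions.columns.tolist(),
            "values": truth.cell_proportions.to_numpy().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_filter_report(report: FilterReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
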