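"""Reading Skyline-style exports and persisting trained models.

Skyline exports chromatograms as delimited tables with one row per trace:
precursor identity, isotope label type, the per-scan times/intensities as
delimited list cells, and the integration boundaries. Report templates vary,
so column names are resolved through an alias table covering both Skyline's
"Results Grid" headers and a canonical snake_case set.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from ._domain import (
    FEATURE_NAMES,
    AnnotatedExample,
    IsotopeTrace,
    PeakFeatures,
    PrecursorPeakGroup,
)
from .errors import FormatError, ModelVersionError, ParseError

__all__ = [
    "COLUMN_ALIASES",
    "read_chromatogram_export",
    "read_precursor_report",
    "read_training_table",
    "load_packaged_training_table",
    "write_feature_table",
    "persist_model",
    "restore_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = "peakvote-model-1"

#: canonical name -> accepted headers (matched case/space/punct-insensitively)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "modified_sequence": (
        "modified_sequence",
        "peptide modified sequence",
        "modified sequence",
        "peptide sequence",
    ),
    "charge": ("charge", "precursor charge"),
    "isotope_label_type": ("isotope_label_type", "isotope label type", "label type", "label"),
    "isotope_index": ("isotope_index", "isotope", "precursor isotope"),
    "fragment_ion": ("fragment_ion", "fragment ion"),
    "times": ("times", "raw times", "chromatogram times"),
    "intensities": ("intensities", "raw intensities", "chromatogram intensities"),
    "boundary_start": ("boundary_start", "min start time", "start time"),
    "boundary_end": ("boundary_end", "max end time", "end time"),
    "idotp": ("idotp", "isotope dot product"),
    "mass_error_ppm": ("mass_error_ppm", "average mass error ppm", "mass error ppm"),
    "area": ("area", "total area"),
    "replicate": ("replicate", "replicate name", "file name"),
    "retention_time": ("retention_time", "best retention time", "retention time"),
}

_LABEL_SYNONYMS = {
    "peptide": "peptide",
    "pep": "peptide",
    "true": "peptide",
    "1": "peptide",
    "noise": "noise",
    "false": "noise",
    "0": "noise",
}


def _norm_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", str(name).strip().lower()).strip()


def _resolve_columns(
    df: pd.DataFrame, column_map: Optional[dict[str, str]] = None
) -> dict[str, str]:
    """Map canonical names to the actual dataframe columns present."""
    found: dict[str, str] = {}
    normalized = {_norm_header(c): c for c in df.columns}
    for canon, aliases in COLUMN_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] in df.columns:
                found[canon] = column_map[canon]
            continue
        for alias in aliases:
            if _norm_header(alias) in normalized:
                found[canon] = normalized[_norm_header(alias)]
                break
    return found


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _parse_list_cell(cell: object, row_id: str, what: str) -> np.ndarray:
    """Parse a comma- or semicolon-delimited numeric list cell."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        raise ParseError(f"row {row_id}: empty {what} cell")
    text = str(cell).strip()
    sep = ";" if ";" in text else ","
    try:
        return np.array([float(tok) for tok in text.split(sep) if tok.strip() != ""])
    except ValueError as exc:
        raise ParseError(f"row {row_id}: unparseable {what} cell ({exc})") from None


_FRAGMENT_ISOTOPE = re.compile(r"\[M\s*\+\s*(\d)\]")


def _isotope_from_row(row: pd.Series, cols: dict[str, str], row_id: str) -> int:
    if "isotope_index" in cols and not pd.isna(row[cols["isotope_index"]]):
        return int(row[cols["isotope_index"]])
    if "fragment_ion" in cols and not pd.isna(row[cols["fragment_ion"]]):
        ion = str(row[cols["fragment_ion"]])
        m = _FRAGMENT_ISOTOPE.search(ion)
        if m:
            return int(m.group(1))
        if "precursor" in ion.lower():
            return 0
    raise ParseError(f"row {row_id}: cannot determine isotope index")


def _opt_float(row: pd.Series, cols: dict[str, str], canon: str) -> Optional[float]:
    if canon not in cols:
        return None
    v = row[cols[canon]]
    if pd.isna(v):
        return None
    return float(v)


def read_chromatogram_export(
    path: str | Path,
    *,
    delimiter: Optional[str] = None,
    time_unit: str = "minutes",
    column_map: Optional[dict[str, str]] = None,
) -> list[PrecursorPeakGroup]:
    """Read a Skyline-style chromatogram export into precursor peak groups.

    One row per isotope trace; rows are grouped by
    (modified sequence, charge, label type, replicate). ``time_unit`` may be
    ``"seconds"`` to convert exported times and boundaries to minutes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter or _sniff_sep(path))
    cols = _resolve_columns(df, column_map)

    required = ["modified_sequence", "charge", "times", "intensities"]
    for canon in required:
        if canon not in cols:
            raise FormatError(f"missing required column: {canon}")
    if "isotope_index" not in cols and "fragment_ion" not in cols:
        raise FormatError("missing required column: isotope_index (or fragment_ion)")

    scale = 1.0 / 60.0 if time_unit == "seconds" else 1.0
    if time_unit not in ("minutes", "seconds"):
        raise ValueError(f"time_unit must be 'minutes' or 'seconds', got {time_unit!r}")

    groups: dict[tuple, PrecursorPeakGroup] = {}
    for idx, row in df.iterrows():
        seq = str(row[cols["modified_sequence"]])
        charge = int(row[cols["charge"]])
        label = "none"
        if "isotope_label_type" in cols and not pd.isna(row[cols["isotope_label_type"]]):
            label = str(row[cols["isotope_label_type"]]).strip().lower()
        replicate = (
            str(row[cols["replicate"]])
            if "replicate" in cols and not pd.isna(row[cols["replicate"]])
            else None
        )
        row_id = f"{idx} ({seq}/{charge}/{label})"

        times = _parse_list_cell(row[cols["times"]], row_id, "times") * scale
        intens = _parse_list_cell(row[cols["intensities"]], row_id, "intensities")
        if times.size != intens.size:
            raise ParseError(
                f"row {row_id}: times ({times.size}) and intensities "
                f"({intens.size}) lengths differ"
            )

        b_start = _opt_float(row, cols, "boundary_start")
        b_end = _opt_float(row, cols, "boundary_end")
        defaulted = b_start is None or b_end is None
        trace = IsotopeTrace(
            isotope_index=_isotope_from_row(row, cols, row_id),
            times=times,
            intensities=intens,
            boundary_start=b_start * scale if b_start is not None else times[0],
            boundary_end=b_end * scale if b_end is not None else times[-1],
            boundary_defaulted=defaulted,
        )

        gkey = (seq, charge, label, replicate)
        if gkey not in groups:
            groups[gkey] = PrecursorPeakGroup(
                modified_sequence=seq, charge=charge, label_type=label, replicate=replicate
            )
        group = groups[gkey]
        group.traces.append(trace)
        seen = [t.isotope_index for t in group.traces]
        if len(seen) != len(set(seen)):
            raise ParseError(f"row {row_id}: duplicate isotope trace in group")

        if group.idotp is None:
            group.idotp = _opt_float(row, cols, "idotp")
        err = _opt_float(row, cols, "mass_error_ppm")
        if err is not None:
            if not isinstance(group.mass_error_ppm, dict):
                group.mass_error_ppm = {}
            group.mass_error_ppm[trace.isotope_index] = err
        area = _opt_float(row, cols, "area")
        if area is not None:
            group.areas[trace.isotope_index] = area
        if group.retention_time is None:
            group.retention_time = _opt_float(row, cols, "retention_time")

    return list(groups.values())


def read_precursor_report(
    path: str | Path,
    *,
    delimiter: Optional[str] = None,
    column_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Read a precursor-level report (idotp, mass error, areas) keyed by
    (modified_sequence, charge, isotope_label_type)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter or _sniff_sep(path))
    cols = _resolve_columns(df, column_map)
    for canon in ("modified_sequence", "charge"):
        if canon not in cols:
            raise FormatError(f"missing required column: {canon}")
    rename = {actual: canon for canon, actual in cols.items()}
    out = df.rename(columns=rename)
    if "isotope_label_type" not in out.columns:
        out["isotope_label_type"] = "none"
    out["isotope_label_type"] = out["isotope_label_type"].str.strip().str.lower()
    return out


def attach_report(
    groups: Iterable[PrecursorPeakGroup], report: pd.DataFrame
) -> list[PrecursorPeakGroup]:
    """Fill idotp / mass error / areas on groups from a precursor report."""
    keyed = {
        (str(r.modified_sequence), int(r.charge), str(r.isotope_label_type)): r
        for r in report.itertuples()
    }
    for g in groups:
        row = keyed.get((g.modified_sequence, g.charge, g.label_type))
        if row is None:
            continue
        if g.idotp is None and hasattr(row, "idotp") and not pd.isna(row.idotp):
            g.idotp = float(row.idotp)
        if (
            g.mass_error_ppm is None
            and hasattr(row, "mass_error_ppm")
            and not pd.isna(row.mass_error_ppm)
        ):
            g.mass_error_ppm = float(row.mass_error_ppm)
    return list(groups)


def read_training_table(path: str | Path) -> list[AnnotatedExample]:
    """Read an annotated feature table (nine features + peptide/noise label).

    Feature columns are matched by their canonical names; missing cells
    become 0 per the global missing-value convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.empty:
        raise FormatError(f"{path}: training table has no rows")

    normalized = {_norm_header(c): c for c in df.columns}
    label_col = None
    for cand in ("label", "annotation", "class"):
        if cand in normalized:
            label_col = normalized[cand]
            break
    if label_col is None:
        raise FormatError(f"{path}: no label/annotation column found")
    missing = [f for f in FEATURE_NAMES if _norm_header(f) not in normalized]
    if missing:
        raise FormatError(f"{path}: missing feature columns: {', '.join(missing)}")

    id_col = normalized.get("source id") or normalized.get("source_id")
    examples = []
    for idx, row in df.iterrows():
        token = str(row[label_col]).strip().lower()
        if token not in _LABEL_SYNONYMS:
            raise FormatError(f"{path}: unrecognized label {row[label_col]!r} in row {idx}")
        values = {}
        for f in FEATURE_NAMES:
            v = row[normalized[_norm_header(f)]]
            values[f] = 0.0 if pd.isna(v) else float(v)
        examples.append(
            AnnotatedExample(
                features=PeakFeatures(**values),
                annotation=_LABEL_SYNONYMS[token],
                source_id=str(row[id_col]) if id_col is not None else f"row{idx}",
            )
        )
    return examples


def load_packaged_training_table() -> list[AnnotatedExample]:
    """Load the packaged SYNTHETIC training table.

    This is a simulator-generated stand-in for a manually annotated
    380-peptide / 357-noise training set, shipped so the full pipeline runs
    with no external download. It is synthetic data, not real annotated
    LC-MS peaks.
    """
    from importlib.resources import files

    path = files("peakvote").joinpath("data/synthetic_training_table.csv")
    return read_training_table(str(path))


def write_feature_table(
    rows: Sequence[AnnotatedExample] | Sequence[PeakFeatures],
    path: str | Path,
    *,
    source_ids: Optional[Sequence[str]] = None,
) -> None:
    """Write features (optionally labelled) as the canonical CSV layout:
    source_id, the nine features in fixed order, and a label column when
    annotations are present."""
    records = []
    for i, row in enumerate(rows):
        if isinstance(row, AnnotatedExample):
            sid, feats, label = row.source_id or f"row{i}", row.features, row.annotation
        else:
            sid = source_ids[i] if source_ids is not None else f"row{i}"
            feats, label = row, None
        rec = {"source_id": sid}
        rec.update({n: getattr(feats, n) for n in FEATURE_NAMES})
        if label is not None:
            rec["label"] = label
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_chromatogram_export(
    groups: Iterable[PrecursorPeakGroup], path: str | Path
) -> None:
    """Write groups as a canonical chromatogram-export TSV (one row per
    trace) that :func:`read_chromatogram_export` round-trips."""
    records = []
    for g in groups:
        err = g.mass_error_ppm
        for tr in sorted(g.traces, key=lambda t: t.isotope_index):
            per_iso_err = err.get(tr.isotope_index) if isinstance(err, dict) else err
            records.append(
                {
                    "modified_sequence": g.modified_sequence,
                    "charge": g.charge,
                    "isotope_label_type": g.label_type,
                    "isotope_index": tr.isotope_index,
                    "times": ",".join(repr(float(v)) for v in tr.times),
                    "intensities": ",".join(repr(float(v)) for v in tr.intensities),
                    "boundary_start": tr.boundary_start,
                    "boundary_end": tr.boundary_end,
                    "idotp": g.idotp,
                    "mass_error_ppm": per_iso_err,
                    "area": g.areas.get(tr.isotope_index),
                    "replicate": g.replicate,
                    "retention_time": g.retention_time,
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def persist_model(model, path: str | Path, *, seed: Optional[int] = None) -> None:
    """Write a trained ensemble to a single versioned archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": seed if seed is not None else getattr(model, "seed", None),
        "ensemble": model,
    }
    joblib.dump(payload, path)


def restore_model(path: str | Path):
    """Restore a trained ensemble written by :func:`persist_model`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = joblib.load(path)
    version = payload.get("format_version") if isinstance(payload, dict) else None
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: model format {version!r} is incompatible with {MODEL_FORMAT_VERSION!r}"
        )
    return payload["ensemble"]
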