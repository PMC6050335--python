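"""Readers and writers for the package's file dialects.

FASTA (via Biopython), TSV site lists, CSV melting/titration curves, and
CSV/JSON results. DNA 'T' is silently normalized to 'U' (with a log note);
all coordinates are 1-based and strands are '+' or '-'.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import BindingModelParams, TitrationCurve
from .errors import ParseError, ValidationError
from .melt import MeltModelParams, MeltingCurve
from .survey import SurveyResult

log = logging.getLogger("m6afold")


# -- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """id → RNA sequence (uppercased, T→U). Duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if "T" in seq:
            log.info("FASTA record %s: DNA 'T' normalized to 'U'", rec.id)
            seq = seq.replace("T", "U")
        records[rec.id] = seq
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# -- site lists ------------------------------------------------------------

def read_site_list(path: str | Path,
                   transcripts: dict[str, str] | None = None):
    """TSV with header transcript_id / position / strand.

    Positions are 1-based; strand is '+' or '-'. Malformed rows (and, when
    `transcripts` is given, out-of-bounds positions or unknown ids) are
    skipped with a per-row report. Returns (sites, report) where sites is a
    list of (transcript_id, position, strand).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "position", "strand"}
    if not required <= set(df.columns):
        raise ParseError(f"site list must have columns {sorted(required)}; "
                         f"found {list(df.columns)}")
    sites, report = [], []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        tid, strand = str(row.transcript_id), str(row.strand)
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            report.append((row_no, f"non-integer position {row.position!r}"))
            continue
        if pos < 1:
            report.append((row_no, f"position {pos} < 1"))
            continue
        if strand not in ("+", "-"):
            report.append((row_no, f"bad strand {strand!r}"))
            continue
        if transcripts is not None:
            if tid not in transcripts:
                report.append((row_no, f"unknown transcript {tid!r}"))
                continue
            if pos > len(transcripts[tid]):
                report.append((row_no, f"position {pos} beyond transcript end"))
                continue
        sites.append((tid, pos, strand))
    for row_no, why in report:
        log.warning("site list %s row %d skipped: %s", path, row_no, why)
    return sites, report


def write_site_list(sites: Iterable[tuple], path: str | Path) -> None:
    pd.DataFrame(sites, columns=["transcript_id", "position", "strand"]).to_csv(
        path, sep="\t", index=False)


# -- curves ----------------------------------------------------------------

def read_melting_csv(path: str | Path, signal_kind: str = "fraction",
                     ct: float | None = None) -> MeltingCurve:
    """CSV with `temperature_C` (or `temperature_K`) and `signal` columns."""
    df = pd.read_csv(path)
    if "temperature_K" in df.columns:
        T = df["temperature_K"].to_numpy(float)
    elif "temperature_C" in df.columns:
        T = df["temperature_C"].to_numpy(float) + 273.15
    else:
        raise ParseError("melting CSV needs a temperature_C or temperature_K column")
    if "signal" not in df.columns:
        raise ParseError("melting CSV needs a signal column")
    return MeltingCurve(T, df["signal"].to_numpy(float),
                        signal_kind=signal_kind, ct=ct)


def write_melting_csv(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temperature_K": curve.temperature,
                  "signal": curve.signal}).to_csv(path, index=False)


def read_titration_csv(path: str | Path, rt: float) -> TitrationCurve:
    """CSV with `protein_conc_M`, `anisotropy`, optional `intensity`."""
    df = pd.read_csv(path)
    for col in ("protein_conc_M", "anisotropy"):
        if col not in df.columns:
            raise ParseError(f"titration CSV needs a {col} column")
    inten = df["intensity"].to_numpy(float) if "intensity" in df.columns else None
    return TitrationCurve(df["protein_conc_M"].to_numpy(float),
                          df["anisotropy"].to_numpy(float), rt, inten)


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    data = {"protein_conc_M": curve.protein_conc, "anisotropy": curve.anisotropy}
    if curve.intensity is not None:
        data["intensity"] = curve.intensity
    pd.DataFrame(data).to_csv(path, index=False)


# -- results ---------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(getattr(k, "value", k)): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_params_json(params: MeltModelParams | BindingModelParams,
                      path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(params), indent=1) + "\n")


def read_params_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_survey_csv(results: Sequence[SurveyResult], path: str | Path) -> None:
    """One row per category per threshold, plus the aggregate 5ʹB fractions."""
    rows = []
    for res in results:
        thr = res.threshold if res.threshold is not None else "mfe"
        for cat, count in res.category_counts.items():
            rows.append({"threshold": thr, "category": cat, "count": count,
                         "fraction": count / res.n_sites if res.n_sites else 0.0})
        rows.append({"threshold": thr, "category": "fiveB_AU_any_structure",
                     "count": round(res.fiveB_AU_fraction * res.n_sites),
                     "fraction": res.fiveB_AU_fraction})
        rows.append({"threshold": thr, "category": "fiveB_AX_any_structure",
                     "count": round(res.fiveB_AX_fraction * res.n_sites),
                     "fraction": res.fiveB_AX_fraction})
    pd.DataFrame(rows).to_csv(path, index=False)
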