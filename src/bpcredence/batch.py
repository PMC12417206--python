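"""Batch evaluation of study tables: CSV in, per-study credence results out.

Input rows carry one study's identifiers plus SBP and DBP summary blocks
(the layout studies typically report: sample size, sampled BP mean ± SD,
error mean ± SD, optional error-BP slope). Each row is evaluated
independently against per-pressure presets; a bad row is flagged and does not
stop the rest of the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ErrorModel
from .model import CredenceModel, CredenceResults, format_percent
from .standards import StandardParams, preset

__all__ = ["StudyRecord", "evaluate_study", "run_batch", "load_demo_studies", "BatchReport"]

logger = logging.getLogger(__name__)

_SUMMARY_COLS = ("mean", "sd", "err_mean", "err_sd", "slope")
_RESULT_FIELDS = ("mu_pmin", "mu_p", "cr_a", "sigma_p", "alpha", "beta")


@dataclass(frozen=True)
class PressureBlock:
    """Summary statistics for one pressure type (SBP or DBP), mmHg."""

    bp_mean: float
    bp_sd: float
    err_mean: float
    err_sd: float
    slope: float = 0.0


@dataclass(frozen=True)
class StudyRecord:
    """One study: identifiers plus SBP and DBP summary blocks."""

    study_id: str
    method_label: str
    n: int
    sbp: PressureBlock
    dbp: PressureBlock

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"{self.study_id}: n must be >= 3; got {self.n}")


def evaluate_study(
    record: StudyRecord, presets: Mapping[str, StandardParams]
) -> dict[str, CredenceResults]:
    """Run the full pipeline for both pressure types of one study.

    ``presets`` maps "sbp" and "dbp" to their StandardParams. Domain errors
    from the core are re-raised with the study id attached.
    """
    out: dict[str, CredenceResults] = {}
    for ptype in ("sbp", "dbp"):
        block: PressureBlock = getattr(record, ptype)
        try:
            em = ErrorModel(
                n=record.n,
                x_bar=block.bp_mean,
                s_x=block.bp_sd,
                y_bar=block.err_mean,
                s_y=block.err_sd,
                beta1=block.slope,
            )
            out[ptype] = CredenceModel(em, presets[ptype]).fit()
        except ValueError as exc:
            raise ValueError(f"study {record.study_id!r} ({ptype.upper()}): {exc}") from exc
        logger.info(
            "study=%s type=%s %s",
            record.study_id,
            ptype.upper(),
            {k: round(v, 6) for k, v in out[ptype].to_dict().items()},
        )
    return out


def _record_from_row(row: pd.Series) -> StudyRecord:
    def block(prefix: str) -> PressureBlock:
        slope_col = f"{prefix}_slope"
        slope = float(row[slope_col]) if slope_col in row.index and pd.notna(row[slope_col]) else 0.0
        return PressureBlock(
            bp_mean=float(row[f"{prefix}_mean"]),
            bp_sd=float(row[f"{prefix}_sd"]),
            err_mean=float(row[f"{prefix}_err_mean"]),
            err_sd=float(row[f"{prefix}_err_sd"]),
            slope=slope,
        )

    return StudyRecord(
        study_id=str(row["study_id"]),
        method_label=str(row.get("method", "")),
        n=int(row["n"]),
        sbp=block("sbp"),
        dbp=block("dbp"),
    )


@dataclass(frozen=True)
class BatchReport:
    """Results table plus per-row errors from one batch run."""

    table: pd.DataFrame
    row_errors: dict[str, str]


def run_batch(
    input_table: str | Path | pd.DataFrame,
    presets: Mapping[str, StandardParams] | None = None,
    output: str | Path | None = None,
) -> BatchReport:
    """Evaluate every study row of a CSV (or DataFrame) table.

    Writes, when ``output`` is given, a CSV (or JSON if the suffix is
    ``.json``) with raw floats at full precision plus percent-formatted
    display columns using the "<0.1%" convention for tiny values. Formatting
    is display-only; raw floats are always emitted alongside.
    """
    if presets is None:
        presets = {"sbp": preset("iso81060_2_sbp")[0], "dbp": preset("iso81060_2_dbp")[0]}
    df = input_table if isinstance(input_table, pd.DataFrame) else pd.read_csv(input_table)
    if df.empty:
        logger.warning("input table is empty: writing an empty report")

    rows, row_errors = [], {}
    for _, raw in df.iterrows():
        sid = str(raw.get("study_id", "?"))
        try:
            record = _record_from_row(raw)
            results = evaluate_study(record, presets)
        except (ValueError, KeyError) as exc:
            row_errors[sid] = str(exc)
            logger.error("study %s failed: %s", sid, exc)
            continue
        out = {"study_id": record.study_id, "method": record.method_label, "n": record.n}
        for ptype, res in results.items():
            for fld in _RESULT_FIELDS:
                out[f"{ptype}_{fld}"] = getattr(res, fld)
            out[f"{ptype}_cr_a_pct"] = format_percent(res.cr_a)
            out[f"{ptype}_mu_p_pct"] = format_percent(res.mu_p)
        rows.append(out)

    table = pd.DataFrame(rows)
    if output is not None:
        output = Path(output)
        if output.suffix.lower() == ".json":
            output.write_text(json.dumps(table.to_dict(orient="records"), indent=2))
        else:
            table.to_csv(output, index=False)  # default float repr round-trips exactly
    return BatchReport(table=table, row_errors=row_errors)


def load_demo_studies() -> pd.DataFrame:
    """Ten published device validation studies shipped as a demo input table."""
    with resources.files("bpcredence").joinpath("data/iso_demo_studies.csv").open() as fh:
        return pd.read_csv(fh)
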