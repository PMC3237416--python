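"""CSV / JSON file interfaces.

All tabular interchange is UTF-8 comma-separated with a header row.
Category and answer tokens are normalised case-insensitively with
whitespace stripped; numeric codes 1-4 are accepted for categories.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .agreement import AgreementReport
from .liverpool import DecisionTree, LiverpoolAssessment, assess
from .naranjo import (
    QUESTION_IDS,
    AnswerSheetError,
    NaranjoAnswerSheet,
    NaranjoResult,
    NaranjoWeightTable,
    naranjo_assess,
)
from .ratings import RatingsMatrix
from .simulate import SimulatedPanel


def read_ratings(path) -> RatingsMatrix:
    """Ratings CSV (first column case id, one column per rater) -> matrix."""
    return RatingsMatrix.from_csv(path)


def write_ratings(matrix: RatingsMatrix, path) -> None:
    matrix.to_csv(path)


def read_naranjo_sheets(path) -> list[tuple[str, str, NaranjoAnswerSheet]]:
    """Answer-sheet CSV with columns case_id, rater_id, Q1..Q10."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["case_id", "rater_id", *QUESTION_IDS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise AnswerSheetError(f"{path}: missing columns {missing}")
    out = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        try:
            sheet = NaranjoAnswerSheet({q: rec[q] for q in QUESTION_IDS})
        except AnswerSheetError as exc:
            raise AnswerSheetError(f"{path}, line {lineno}: {exc}") from None
        out.append((rec["case_id"], rec["rater_id"], sheet))
    return out


def score_naranjo_file(
    input_path, output_path, weights: NaranjoWeightTable | None = None
) -> pd.DataFrame:
    """Score every sheet in a CSV; write case_id, rater_id, total, category."""
    weights = weights or NaranjoWeightTable.default()
    rows = []
    for case_id, rater_id, sheet in read_naranjo_sheets(input_path):
        result: NaranjoResult = naranjo_assess(sheet, weights)
        rows.append(
            {
                "case_id": case_id,
                "rater_id": rater_id,
                "total": result.total,
                "category": result.category.label,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(output_path, index=False)
    return frame


def read_liverpool_sheets(path) -> list[tuple[str, str, dict[str, str]]]:
    """Sheet CSV with columns case_id, rater_id, one per node id; blank =
    unvisited."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("case_id", "rater_id"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    node_cols = [c for c in frame.columns if c not in ("case_id", "rater_id")]
    out = []
    for row in frame.itertuples(index=False):
        rec = dict(zip(frame.columns, row))
        answers = {c: rec[c].strip() for c in node_cols if str(rec[c]).strip()}
        out.append((rec["case_id"], rec["rater_id"], answers))
    return out


def assess_liverpool_file(
    tree: DecisionTree, input_path, output_path, explain: bool = False
) -> pd.DataFrame:
    """Assess every sheet in a CSV; optionally append the traversal path."""
    rows = []
    for case_id, rater_id, answers in read_liverpool_sheets(input_path):
        result: LiverpoolAssessment = assess(tree, answers)
        row = {
            "case_id": case_id,
            "rater_id": rater_id,
            "category": result.category.label,
        }
        if explain:
            row["path"] = " -> ".join(f"{n}={a}" for n, a in result.path)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(output_path, index=False)
    return frame


def write_report(report: AgreementReport, path, format: str = "json") -> None:
    """Serialise an agreement report as machine JSON or a markdown table."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif format in ("md", "markdown"):
        path.write_text(report.to_markdown() + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def write_panel(panel: SimulatedPanel, out_dir) -> dict[str, Path]:
    """Write latent.csv, ratings.csv and (when present) sheets.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    latent = pd.DataFrame(
        {
            "case_id": panel.ratings.case_ids,
            "latent_category": [c.label for c in panel.latent_categories],
        }
    )
    paths["latent"] = out / "latent.csv"
    latent.to_csv(paths["latent"], index=False)

    paths["ratings"] = out / "ratings.csv"
    panel.ratings.to_csv(paths["ratings"])

    if panel.sheets is not None:
        node_ids = sorted({n for ans in panel.sheets.values() for n in ans})
        rows = []
        for (case_id, rater_id), answers in panel.sheets.items():
            row = {"case_id": case_id, "rater_id": rater_id}
            row.update({n: answers.get(n, "") for n in node_ids})
            rows.append(row)
        paths["sheets"] = out / "sheets.csv"
        pd.DataFrame(rows).to_csv(paths["sheets"], index=False)
    return paths


def file_digest(path) -> str:
    """Short sha256 digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]
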