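"""Readers and writers for DREAM-layout files.

Formats (all UTF-8 tab-separated text, Unix or Windows line endings):

* expression matrix — header row of gene ids, one row per experimental
  condition.  Some distributions quote the header ids and some prepend a
  row-label column; both dialects are auto-detected.
* regulator list — one gene id per line.
* gold standard — ``regulator<TAB>target<TAB>label`` with label 1 for a
  known interaction; label-0 lines, when present, define the eligible
  negative universe.
* predictions — ``regulator<TAB>target<TAB>score`` sorted by descending
  score (the standard DREAM submission format).

Readers reject malformed input (with row/column coordinates) rather than
silently coercing it.  Gene identity is the header string, matched
case-sensitively.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import GoldStandard

__all__ = [
    "DatasetBundle",
    "read_expression",
    "write_expression",
    "read_regulators",
    "read_gold",
    "write_gold",
    "read_predictions",
    "write_predictions",
    "load_bundle",
]

# scores are serialized with this many significant digits
SCORE_DIGITS = 6


def _open_rows(path):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return list(csv.reader(fh, delimiter="\t"))


def read_expression(path) -> pd.DataFrame:
    """Read a conditions x genes expression matrix.

    Returns a DataFrame with gene ids as columns.  A leading row-label
    column (non-numeric first field, or one more field per data row than
    header entries) is detected and dropped.

    Raises
    ------
    ValidationError
        On duplicate gene ids, missing values, non-numeric cells (with
        row/column coordinates), or a matrix smaller than 3 x 2.
    """
    rows = [r for r in _open_rows(path) if r and any(f.strip() for f in r)]
    if len(rows) < 2:
        raise ValidationError(f"{path}: expression file needs a header and data rows")
    header = [h.strip() for h in rows[0]]
    data_rows = rows[1:]

    genes = header
    if all(len(r) == len(header) + 1 for r in data_rows):
        # row-label column whose field is absent from the header
        data_rows = [r[1:] for r in data_rows]
    elif data_rows and len(data_rows[0]) == len(header):
        try:
            float(data_rows[0][0])
        except ValueError:
            # row-label column with its own header entry
            genes = header[1:]
            data_rows = [r[1:] for r in data_rows]

    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate gene ids in header: {sorted(dupes)}")
    values = np.empty((len(data_rows), len(genes)))
    for i, row in enumerate(data_rows):
        if len(row) != len(genes):
            raise ValidationError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(genes)}"
            )
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                raise ValidationError(
                    f"{path}: missing value at row {i + 2}, column {genes[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, "
                    f"column {genes[j]!r}"
                ) from None
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValidationError(
            f"{path}: need at least 3 conditions and 2 genes, got {values.shape}"
        )
    return pd.DataFrame(values, columns=genes)


def write_expression(data: pd.DataFrame, path) -> None:
    """Write an expression matrix as header + numeric rows (no index)."""
    data.to_csv(path, sep="\t", index=False)


def read_regulators(path) -> list:
    """Read a regulator list, de-duplicated and order-preserving."""
    with open(path, "r", encoding="utf-8") as fh:
        seen = {}
        for line in fh:
            g = line.strip()
            if g:
                seen.setdefault(g, None)
    if not seen:
        raise ValidationError(f"{path}: regulator file is empty")
    return list(seen)


def write_regulators(regulators, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in regulators:
            fh.write(f"{g}\n")


def read_gold(path) -> GoldStandard:
    """Read a 3-column gold standard file.

    Label-1 lines are positives.  If any label-0 lines are present, the
    eligible universe is positives plus the label-0 pairs; otherwise the
    universe defaults to all non-self regulator x gene pairs over the ids
    in the file (regulators = ids appearing as sources).
    """
    positives = set()
    negatives = set()
    for i, row in enumerate(_open_rows(path), start=1):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) != 3:
            raise ValidationError(
                f"{path}: line {i}: expected 3 tab-separated fields, got {len(row)}"
            )
        r, t, label = (f.strip() for f in row)
        if r == t:
            raise ValidationError(f"{path}: line {i}: self-edge {r!r}")
        if label == "1":
            positives.add((r, t))
        elif label == "0":
            negatives.add((r, t))
        else:
            raise ValidationError(f"{path}: line {i}: label must be 0 or 1, got {label!r}")
    if negatives:
        return GoldStandard(
            positives=frozenset(positives),
            eligible_pairs=frozenset(positives | negatives),
        )
    return GoldStandard(positives=frozenset(positives))


def write_gold(gold: GoldStandard, path) -> None:
    """Write positives (label 1) and, when the universe is explicit, the
    remaining eligible pairs as label-0 lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for r, t in sorted(gold.positives):
            fh.write(f"{r}\t{t}\t1\n")
        if gold.eligible_pairs is not None:
            for r, t in sorted(gold.eligible_pairs - gold.positives):
                fh.write(f"{r}\t{t}\t0\n")


def write_predictions(edges: pd.DataFrame, path) -> None:
    """Write a ranked edge list; scores carry 6 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.regulator}\t{row.target}\t{row.score:.{SCORE_DIGITS}g}\n")


def read_predictions(path) -> pd.DataFrame:
    """Read a ranked edge list, validating order and edge sanity."""
    records = []
    seen = set()
    for i, row in enumerate(_open_rows(path), start=1):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) != 3:
            raise ValidationError(
                f"{path}: line {i}: expected 3 tab-separated fields, got {len(row)}"
            )
        r, t, s = (f.strip() for f in row)
        if r == t:
            raise ValidationError(f"{path}: line {i}: self-edge {r!r}")
        if (r, t) in seen:
            raise ValidationError(f"{path}: line {i}: duplicate edge ({r!r}, {t!r})")
        seen.add((r, t))
        try:
            score = float(s)
        except ValueError:
            raise ValidationError(
                f"{path}: line {i}: non-numeric score {s!r}"
            ) from None
        records.append((r, t, score))
    df = pd.DataFrame(records, columns=["regulator", "target", "score"])
    if len(df) > 1 and np.any(np.diff(df["score"].to_numpy()) > 0):
        raise ValidationError(f"{path}: scores are not non-increasing")
    return df


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class DatasetBundle:
    """An expression matrix with optional regulator list and gold standard,
    cross-validated so that every id resolves to an expression gene."""

    expression: pd.DataFrame
    regulators: list | None
    gold: GoldStandard | None
    provenance: dict


def load_bundle(expression_path, regulators_path=None, gold_path=None) -> DatasetBundle:
    """Load and cross-validate a dataset.

    Raises
    ------
    ValidationError
        If a regulator or gold-standard id does not resolve to a gene of
        the expression matrix.
    """
    expression = read_expression(expression_path)
    genes = set(expression.columns)
    provenance = {"expression": {"path": str(expression_path), "sha256": _digest(expression_path)}}

    regulators = None
    if regulators_path is not None:
        regulators = read_regulators(regulators_path)
        unknown = [r for r in regulators if r not in genes]
        if unknown:
            raise ValidationError(
                f"{regulators_path}: regulators not in expression matrix: {unknown}"
            )
        provenance["regulators"] = {
            "path": str(regulators_path),
            "sha256": _digest(regulators_path),
        }

    gold = None
    if gold_path is not None:
        gold = read_gold(gold_path)
        ids = {g for pair in gold.universe() for g in pair}
        unknown = sorted(ids - genes)
        if unknown:
            raise ValidationError(
                f"{gold_path}: gold-standard ids not in expression matrix: {unknown}"
            )
        provenance["gold"] = {"path": str(gold_path), "sha256": _digest(gold_path)}

    return DatasetBundle(
        expression=expression, regulators=regulators, gold=gold, provenance=provenance
    )
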