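"""Minimal reader/writer for the MEKA multi-label ARFF dialect.

Supports the subset of ARFF needed for multi-label work: numeric/real/integer
attributes, nominal attributes, dense and sparse data rows, and a relation
name carrying the MEKA ``-C <q>`` label-count token.  Comment lines (``%``)
and blank lines are ignored.  Missing values (``?``) are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["ArffParseError", "parse_arff", "write_arff", "meka_label_count"]


class ArffParseError(ValueError):
    """Malformed ARFF input; the message names the offending line."""


@dataclass
class _Attribute:
    name: str
    kind: str  # "numeric" or "nominal"
    values: tuple[str, ...] = ()  # nominal domain, in declaration order


_RELATION_RE = re.compile(r"@relation\s+(.+)", re.IGNORECASE)
_ATTRIBUTE_RE = re.compile(r"@attribute\s+(\S+|'[^']*')\s+(.+)", re.IGNORECASE)


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def meka_label_count(relation: str) -> int | None:
    """Extract ``q`` from a MEKA relation name like ``"toy: -C 6"``."""
    match = re.search(r"-C\s+(-?\d+)", relation)
    if match is None:
        return None
    return int(match.group(1))


def parse_arff(text: str) -> tuple[str, list[_Attribute], np.ndarray]:
    """Parse ARFF text into (relation, attributes, dense value matrix).

    Nominal cell values are returned as the *index* into the attribute's
    declared domain; numeric cells as floats.
    """
    relation = ""
    attributes: list[_Attribute] = []
    rows: list[np.ndarray] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        lowered = line.lower()
        if not in_data:
            if lowered.startswith("@relation"):
                m = _RELATION_RE.match(line)
                if m is None:
                    raise ArffParseError(f"line {lineno}: malformed @relation")
                relation = _unquote(m.group(1))
            elif lowered.startswith("@attribute"):
                m = _ATTRIBUTE_RE.match(line)
                if m is None:
                    raise ArffParseError(f"line {lineno}: malformed @attribute")
                name, spec = _unquote(m.group(1)), m.group(2).strip()
                if spec.startswith("{"):
                    if not spec.endswith("}"):
                        raise ArffParseError(
                            f"line {lineno}: unterminated nominal domain"
                        )
                    values = tuple(
                        _unquote(v) for v in spec[1:-1].split(",") if v.strip() != ""
                    )
                    attributes.append(_Attribute(name, "nominal", values))
                elif spec.lower() in {"numeric", "real", "integer"}:
                    attributes.append(_Attribute(name, "numeric"))
                else:
                    raise ArffParseError(
                        f"line {lineno}: unsupported attribute type {spec!r}"
                    )
            elif lowered.startswith("@data"):
                if not attributes:
                    raise ArffParseError(f"line {lineno}: @data before @attribute")
                in_data = True
            else:
                raise ArffParseError(f"line {lineno}: unrecognized header line")
            continue
        rows.append(_parse_data_row(line, attributes, lineno))
    if not in_data:
        raise ArffParseError("missing @data section")
    data = (
        np.vstack(rows) if rows else np.empty((0, len(attributes)), dtype=float)
    )
    return relation, attributes, data


def _parse_data_row(
    line: str, attributes: list[_Attribute], lineno: int
) -> np.ndarray:
    n = len(attributes)
    if line.startswith("{"):  # sparse row: unlisted cells are 0 / first nominal
        if not line.endswith("}"):
            raise ArffParseError(f"line {lineno}: unterminated sparse row")
        row = np.zeros(n, dtype=float)
        body = line[1:-1].strip()
        entries = [e for e in body.split(",") if e.strip()] if body else []
        for entry in entries:
            parts = entry.strip().split(None, 1)
            if len(parts) != 2:
                raise ArffParseError(f"line {lineno}: malformed sparse entry")
            idx = int(parts[0])
            if not 0 <= idx < n:
                raise ArffParseError(f"line {lineno}: sparse index {idx} out of range")
            row[idx] = _parse_cell(parts[1], attributes[idx], lineno)
        return row
    cells = [c.strip() for c in line.split(",")]
    if len(cells) != n:
        raise ArffParseError(
            f"line {lineno}: expected {n} values, found {len(cells)}"
        )
    return np.array(
        [_parse_cell(c, a, lineno) for c, a in zip(cells, attributes)], dtype=float
    )


def _parse_cell(token: str, attribute: _Attribute, lineno: int) -> float:
    token = _unquote(token)
    if token == "?":
        raise ArffParseError(
            f"line {lineno}: missing value in attribute {attribute.name!r}"
        )
    if attribute.kind == "nominal":
        try:
            return float(attribute.values.index(token))
        except ValueError:
            raise ArffParseError(
                f"line {lineno}: value {token!r} not in nominal domain of "
                f"{attribute.name!r}"
            ) from None
    try:
        return float(token)
    except ValueError:
        raise ArffParseError(
            f"line {lineno}: non-numeric value {token!r} in attribute "
            f"{attribute.name!r}"
        ) from None


def _quote(name: str) -> str:
    if re.search(r"[\s,{}%']", name) or name == "":
        return "'" + name.replace("'", "\\'") + "'"
    return name


def write_arff(
    relation: str,
    label_names: list[str],
    feature_names: list[str],
    labels: np.ndarray,
    features: np.ndarray,
) -> str:
    """Serialize a multi-label dataset as MEKA ARFF (labels first, {0,1})."""
    lines = [f"@relation {_quote(relation)}", ""]
    for name in label_names:
        lines.append(f"@attribute {_quote(name)} {{0,1}}")
    for name in feature_names:
        lines.append(f"@attribute {_quote(name)} numeric")
    lines.append("")
    lines.append("@data")
    for yrow, xrow in zip(labels, features):
        cells = [str(int(v)) for v in yrow] + [repr(float(v)) for v in xrow]
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"
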