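"""Plain-text named-vector I/O for survival assays.

The file format is line oriented: ``#`` starts a comment line, every data
line is ``name:v1,v2,...``.  An experiment with index *i* is assembled from
the quadruple ``C<i>`` (exposure concentrations), ``Ct<i>`` (exposure
times), ``y<i>`` (survivor counts) and ``yt<i>`` (observation times);
grouping is by the numeric suffix, not by file order.

The packaged ``diazinon`` fixture contains three pulsed-exposure toxicity
experiments with the freshwater amphipod *Gammarus pulex* (70 individuals
each, concentrations in nmol/l, times in days).
"""

from __future__ import annotations

import re
from importlib import resources
from os import PathLike
from pathlib import Path

import numpy as np

from .data_model import SurvivalExperiment, make_experiment

__all__ = [
    "ParseError",
    "read_named_vectors",
    "read_experiment_list",
    "write_experiment_list",
    "load_diazinon",
]

_DATA_LINE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*:\s*(.*)$")
_QUAD_NAME = re.compile(r"^(Ct|C|yt|y)(\d+)$")


class ParseError(ValueError):
    """Malformed named-vector text."""


def _looks_like_path(source) -> bool:
    if isinstance(source, PathLike):
        return True
    return isinstance(source, str) and "\n" not in source and ":" not in source


def read_named_vectors(source) -> dict[str, np.ndarray]:
    """Parse named-vector text (path or literal text) into an ordered dict."""
    if _looks_like_path(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    entries: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _DATA_LINE.match(line)
        if m is None:
            raise ParseError(f"line {lineno}: expected 'name:v1,v2,...', got {raw!r}")
        name, payload = m.group(1), m.group(2)
        if name in entries:
            raise ParseError(f"line {lineno}: duplicate name {name!r}")
        items = [tok.strip() for tok in payload.split(",")]
        try:
            values = np.asarray([float(tok) for tok in items], dtype=float)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unparseable number in {name!r}: {exc}") from None
        entries[name] = values
    return entries


def read_experiment_list(source) -> list[SurvivalExperiment]:
    """Read experiments from a named-vector file (path) or literal text.

    Quadruples (C<i>, Ct<i>, y<i>, yt<i>) are matched by numeric suffix and
    validated; an incomplete quadruple or a file without any experiment is
    an error.
    """
    entries = read_named_vectors(source)
    groups: dict[int, dict[str, np.ndarray]] = {}
    for name, values in entries.items():
        m = _QUAD_NAME.match(name)
        if m is None:
            continue
        prefix, idx = m.group(1), int(m.group(2))
        groups.setdefault(idx, {})[prefix] = values
    if not groups:
        raise ParseError("no experiments found")
    experiments = []
    for idx in sorted(groups):
        g = groups[idx]
        missing = sorted({"C", "Ct", "y", "yt"} - set(g))
        if missing:
            raise ParseError(
                f"experiment {idx}: missing member(s) {missing} of quadruple "
                f"(C{idx}, Ct{idx}, y{idx}, yt{idx})"
            )
        experiments.append(
            make_experiment(g["C"], g["Ct"], g["y"], g["yt"], label=str(idx))
        )
    return experiments


def _render(v: float) -> str:
    # repr round-trips doubles exactly; trim the trailing '.0' of integers
    s = repr(float(v))
    return s[:-2] if s.endswith(".0") else s


def write_experiment_list(experiments, path, comment: str | None = None) -> None:
    """Write experiments in the named-vector format (readable back exactly)."""
    experiments = list(experiments)
    if not experiments:
        raise ValueError("cannot write an empty experiment list")
    lines = []
    if comment:
        lines.append(f"# {comment}")
    for i, exp in enumerate(experiments, start=1):
        lines.append(f"C{i}:" + ",".join(_render(v) for v in exp.exposure.conc))
        lines.append(f"Ct{i}:" + ",".join(_render(v) for v in exp.exposure.times))
        lines.append(f"y{i}:" + ",".join(str(int(v)) for v in exp.survival.counts))
        lines.append(f"yt{i}:" + ",".join(_render(v) for v in exp.survival.times))
    Path(path).write_text("\n".join(lines) + "\n")


def load_diazinon() -> list[SurvivalExperiment]:
    """Load the packaged diazinon dataset (3 experiments, 70 individuals each)."""
    text = resources.files("guts").joinpath("data/diazinon.txt").read_text()
    return read_experiment_list(text)


def write_table_csv(table, path) -> None:
    """Write a result table (pandas DataFrame) as CSV with a header row."""
    table.to_csv(path, index=False)
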