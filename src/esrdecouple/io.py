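"""Read and write spectra as comment-headered two-column text files.

The canonical on-disk format is CSV with ``#``-prefixed header lines of the
form ``# key: value`` carrying the microwave frequency, the field unit and
free provenance, followed by ``field,intensity`` rows.  Fields are stored
in Gauss; milliTesla input is converted on read.  A write-then-read round
trip reproduces the spectrum bit-for-bit in value and metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SpectrumFormatError
from .spectrum import UNIFORMITY_RTOL, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["SpectrumFileDialect", "read_spectrum", "write_spectrum"]


@dataclass(frozen=True)
class SpectrumFileDialect:
    delimiter: str = ","
    comment: str = "#"
    field_first: bool = True
    field_unit: str = "G"  # 'G' or 'mT'


DEFAULT_DIALECT = SpectrumFileDialect()


def write_spectrum(
    spec: Spectrum, path: str | Path, dialect: SpectrumFileDialect = DEFAULT_DIALECT
) -> None:
    """Write ``spec`` deterministically (same bytes for same input)."""
    path = Path(path)
    c = dialect.comment
    lines = [f"{c} esrdecouple spectrum", f"{c} field_unit: {dialect.field_unit}"]
    if spec.mw_freq_GHz is not None:
        lines.append(f"{c} mw_freq_GHz: {spec.mw_freq_GHz:.10g}")
    for key in sorted(spec.meta):
        val = spec.meta[key]
        if isinstance(val, (str, int, float, bool)):
            lines.append(f"{c} {key}: {val}")
    scale = 0.1 if dialect.field_unit == "mT" else 1.0
    for b, y in zip(spec.field, spec.intensity):
        pair = (b * scale, y) if dialect.field_first else (y, b * scale)
        lines.append(f"{pair[0]:.17g}{dialect.delimiter}{pair[1]:.17g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_headers(text_lines: list[str], comment: str) -> dict[str, str]:
    headers: dict[str, str] = {}
    for raw in text_lines:
        body = raw[len(comment):].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            headers[key.strip()] = val.strip()
    return headers


def read_spectrum(
    path: str | Path, dialect: SpectrumFileDialect = DEFAULT_DIALECT
) -> Spectrum:
    """Read a two-column spectrum file.

    The field axis is sorted ascending if needed; spacing non-uniformity
    beyond 0.1% triggers linear resampling onto a uniform grid (logged).
    A missing microwave frequency is not an error here — operations that
    need g values fail at their own call site.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    comment_lines = [ln for ln in raw if ln.startswith(dialect.comment)]
    headers = _parse_headers(comment_lines, dialect.comment)

    field_vals: list[float] = []
    int_vals: list[float] = []
    for lineno, ln in enumerate(raw, start=1):
        s = ln.strip()
        if not s or s.startswith(dialect.comment):
            continue
        parts = s.split(dialect.delimiter) if dialect.delimiter.strip() else s.split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected >=2 columns, got {s!r}")
        try:
            a, b = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: unparseable row {s!r}") from exc
        field_vals.append(a if dialect.field_first else b)
        int_vals.append(b if dialect.field_first else a)
    if not field_vals:
        raise SpectrumFormatError(f"{path}: no data rows")

    field = np.asarray(field_vals)
    intensity = np.asarray(int_vals)
    unit = headers.get("field_unit", dialect.field_unit)
    if unit == "mT":
        field = field * 10.0
    elif unit != "G":
        raise SpectrumFormatError(f"{path}: unknown field unit {unit!r}")

    order = np.argsort(field)
    if not np.array_equal(order, np.arange(field.size)):
        field, intensity = field[order], intensity[order]
    steps = np.diff(field)
    if np.any(steps <= 0):
        raise SpectrumFormatError(f"{path}: duplicate field values")
    mean = steps.mean()
    if np.max(np.abs(steps - mean)) > UNIFORMITY_RTOL * mean:
        logger.warning("%s: non-uniform field spacing; resampling to uniform grid", path)
        uniform = np.linspace(field[0], field[-1], field.size)
        intensity = np.interp(uniform, field, intensity)
        field = uniform

    mw = headers.get("mw_freq_GHz")
    meta = {
        k: v for k, v in headers.items() if k not in ("mw_freq_GHz", "field_unit")
    }
    meta["source"] = str(path)
    return Spectrum(
        field=field,
        intensity=intensity,
        mw_freq_GHz=float(mw) if mw is not None else None,
        meta=meta,
    )
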