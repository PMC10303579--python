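"""Field-swept first-derivative EPR spectrum container and file dialects.

A :class:`Spectrum` holds a uniformly spaced magnetic-field axis (gauss), a
first-derivative intensity trace (arbitrary units) and acquisition metadata
(temperature, spin label, membrane class, retinoid condition).  Two text
dialects are supported:

``two_column``
    ``#``-prefixed ``key: value`` header lines followed by two whitespace
    separated columns (field_G, intensity).

``jcamp_subset``
    A narrow JCAMP-DX-style dialect: ``##KEY=value`` labelled records and an
    ``##XYDATA=(XY..XY)`` table with one ``x, y`` pair per line.  It is not
    a general JCAMP reader; it reads exactly what :func:`write_spectrum`
    emits plus simple hand-edited variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumMeta",
    "SpectrumError",
    "SpectrumParseError",
    "SPIN_LABELS",
    "read_spectrum",
    "write_spectrum",
]

#: Recognised spin labels: headgroup (T-PC) and chain-carbon doxyl labels.
SPIN_LABELS = ("T-PC", "5-PC", "7-PC", "10-PC", "12-PC", "16-PC")

_UNIFORMITY_RTOL = 1e-6
_MIN_POINTS = 64


class SpectrumError(ValueError):
    """Invalid spectrum data."""


class SpectrumParseError(SpectrumError):
    """Unparseable spectrum file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


@dataclass
class SpectrumMeta:
    """Acquisition metadata carried with every spectrum."""

    temperature_K: float = 298.0
    spin_label: str = "16-PC"
    membrane_class: str = "custom"
    retinoid_condition: str = "control"
    sweep_center_G: float = 3350.0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise SpectrumError(f"temperature must be positive, got {self.temperature_K}")


@dataclass
class Spectrum:
    """Uniformly sampled first-derivative EPR trace."""

    field: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("field and intensity must be 1-D")
        if self.field.size != self.intensity.size:
            raise SpectrumError(
                f"length mismatch: {self.field.size} field vs "
                f"{self.intensity.size} intensity points"
            )
        if self.field.size < _MIN_POINTS:
            raise SpectrumError(f"need >= {_MIN_POINTS} points, got {self.field.size}")
        steps = np.diff(self.field)
        if np.any(steps <= 0):
            raise SpectrumError("field axis must be strictly increasing")
        step = steps.mean()
        # tolerance scales with the field magnitude: text dialects store
        # absolute field values at finite precision, so step-relative
        # uniformity cannot be demanded at 3350 G
        tol = _UNIFORMITY_RTOL * max(1.0, float(np.max(np.abs(self.field))))
        if np.max(np.abs(steps - step)) > tol:
            raise SpectrumError("field axis must be uniformly spaced")
        if not (np.all(np.isfinite(self.field)) and np.all(np.isfinite(self.intensity))):
            raise SpectrumError("non-finite values in spectrum")

    @property
    def step(self) -> float:
        """Field step in gauss."""
        return float((self.field[-1] - self.field[0]) / (self.field.size - 1))

    @property
    def n_points(self) -> int:
        return int(self.field.size)


_META_FIELDS = {
    "temperature_K": float,
    "spin_label": str,
    "membrane_class": str,
    "retinoid_condition": str,
    "sweep_center_G": float,
    "notes": str,
}


def _meta_from_dict(raw: dict[str, str]) -> SpectrumMeta:
    kwargs = {}
    for key, cast in _META_FIELDS.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    return SpectrumMeta(**kwargs)


def _read_two_column(path: Path) -> Spectrum:
    raw_meta: dict[str, str] = {}
    fields: list[float] = []
    values: list[float] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            body = text.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                raw_meta[key.strip()] = val.strip()
            continue
        parts = text.split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"expected two columns, got {len(parts)}", line=lineno
            )
        try:
            fields.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(f"unparseable number in {text!r}", line=lineno)
    try:
        return Spectrum(np.array(fields), np.array(values), _meta_from_dict(raw_meta))
    except SpectrumError as exc:
        raise SpectrumParseError(f"invalid spectrum in {path.name}: {exc}") from exc


def _read_jcamp(path: Path) -> Spectrum:
    raw_meta: dict[str, str] = {}
    fields: list[float] = []
    values: list[float] = []
    in_table = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("##"):
            key, _, val = text[2:].partition("=")
            key = key.strip()
            val = val.strip()
            if key.upper() == "XYDATA":
                in_table = True
                continue
            if key.upper() == "END":
                in_table = False
                continue
            if key.startswith("$"):  # private labels carry our metadata, case-sensitive
                raw_meta[key[1:].strip()] = val
            else:
                raw_meta[key.lower()] = val
            continue
        if in_table:
            parts = [p for p in text.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"expected 'x, y' pair, got {text!r}", line=lineno
                )
            try:
                fields.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(f"unparseable number in {text!r}", line=lineno)
    try:
        return Spectrum(np.array(fields), np.array(values), _meta_from_dict(raw_meta))
    except SpectrumError as exc:
        raise SpectrumParseError(f"invalid spectrum in {path.name}: {exc}") from exc


def read_spectrum(path, dialect: str = "two_column") -> Spectrum:
    """Read a spectrum file.

    Parameters
    ----------
    path : file path
    dialect : {"two_column", "jcamp_subset"}
    """
    path = Path(path)
    if dialect == "two_column":
        return _read_two_column(path)
    if dialect == "jcamp_subset":
        return _read_jcamp(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(spec: Spectrum, path, dialect: str = "two_column") -> None:
    """Write a spectrum losslessly re-readable by :func:`read_spectrum`."""
    if not isinstance(spec, Spectrum):
        raise SpectrumError("write_spectrum expects a Spectrum")
    path = Path(path)
    meta = spec.meta
    if dialect == "two_column":
        lines = [
            "# memepr spectrum (field_G  intensity)",
        ]
        for key in _META_FIELDS:
            lines.append(f"# {key}: {getattr(meta, key)}")
        lines += [
            f"{b:.10g}\t{y:.12g}" for b, y in zip(spec.field, spec.intensity)
        ]
    elif dialect == "jcamp_subset":
        lines = [
            "##TITLE=memepr spectrum",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=EPR SPECTRUM",
            "##XUNITS=GAUSS",
            "##YUNITS=ARBITRARY UNITS",
            f"##NPOINTS={spec.n_points}",
        ]
        for key in _META_FIELDS:
            lines.append(f"##${key}={getattr(meta, key)}")
        lines.append("##XYDATA=(XY..XY)")
        lines += [f"{b:.10g}, {y:.12g}" for b, y in zip(spec.field, spec.intensity)]
        lines.append("##END=")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
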