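"""Spectrum container, plain-text spectrum I/O and dataset manifests.

File dialect: two numeric columns (wavenumber cm-1, intensity a.u.) separated
by whitespace or a comma, with optional ``#``-prefixed lines.  Header lines of
the form ``# key: value`` carry provenance metadata (species, fraction_pct,
region, replicate, normalization flags) and survive a write/read round trip.
Wavenumbers are cm-1 throughout; duplicate wavenumbers are rejected rather
than averaged, since coincident points usually indicate an export fault.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .exceptions import (
    CoverageError,
    ManifestError,
    SpectrumParseError,
    SpectrumValidationError,
)

__all__ = [
    "Spectrum",
    "ManifestEntry",
    "DatasetManifest",
    "read_spectrum",
    "write_spectrum",
    "load_manifest",
    "save_manifest",
    "REGIONS",
]

#: region tag -> axis coverage requirement
REGIONS = ("fingerprint", "thz", "sers")
_REGION_SPAN = {"fingerprint": (900.0, 1700.0), "sers": (400.0, 1800.0)}
_MIN_POINTS_TAGGED = 8


@dataclass(frozen=True)
class Spectrum:
    """A Raman spectrum: strictly increasing wavenumber axis plus intensities.

    Metadata fields record provenance (species or ``"mixture"``, nominal
    oxidized fraction in %, replicate id) and processing state
    (``baseline_corrected``, ``normalized`` in {None, "reference", "unit"}).
    A ``region`` tag, when present, asserts axis coverage: ``thz`` spectra
    must reach below 100 cm-1, ``fingerprint`` must span 900-1700 cm-1 and
    ``sers`` must span 400-1800 cm-1; tagged spectra need >= 8 points.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    species: str | None = None
    fraction_pct: float | None = None
    region: str | None = None
    replicate: int | None = None
    baseline_corrected: bool = False
    normalized: str | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)
        if wn.ndim != 1 or inten.ndim != 1:
            raise SpectrumValidationError("wavenumbers and intensities must be 1-D")
        if wn.size != inten.size:
            raise SpectrumValidationError(
                f"axis length {wn.size} != intensity length {inten.size}"
            )
        if wn.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(inten))):
            raise SpectrumValidationError("non-finite value in spectrum")
        if np.any(np.diff(wn) <= 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        if self.fraction_pct is not None and not (
            0.0 <= float(self.fraction_pct) <= 100.0
        ):
            raise SpectrumValidationError(
                f"oxidized fraction {self.fraction_pct} outside [0, 100]"
            )
        if self.region is not None:
            self._check_region(wn)

    def _check_region(self, wn: np.ndarray) -> None:
        if self.region not in REGIONS:
            raise SpectrumValidationError(
                f"unknown region tag {self.region!r}; expected one of {REGIONS}"
            )
        if wn.size < _MIN_POINTS_TAGGED:
            raise SpectrumValidationError(
                f"{self.region} spectrum needs >= {_MIN_POINTS_TAGGED} points, got {wn.size}"
            )
        if self.region == "thz":
            if wn.min() >= 100.0:
                raise SpectrumValidationError(
                    "thz spectrum must cover frequencies below 100 cm-1"
                )
        else:
            lo, hi = _REGION_SPAN[self.region]
            if wn.min() > lo or wn.max() < hi:
                raise SpectrumValidationError(
                    f"{self.region} spectrum must cover {lo}-{hi} cm-1, "
                    f"axis spans {wn.min()}-{wn.max()}"
                )

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def covers(self, lo: float, hi: float) -> bool:
        return bool(self.wavenumbers.min() <= lo and self.wavenumbers.max() >= hi)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to the closed interval [lo, hi] (region tag dropped)."""
        if not self.covers(lo, hi):
            raise CoverageError(
                f"window [{lo}, {hi}] not covered by axis "
                f"[{self.wavenumbers.min()}, {self.wavenumbers.max()}]"
            )
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return self.replace(
            wavenumbers=self.wavenumbers[mask],
            intensities=self.intensities[mask],
            region=None,
        )


_META_FIELDS = (
    "species",
    "fraction_pct",
    "region",
    "replicate",
    "baseline_corrected",
    "normalized",
)


def read_spectrum(path: str | Path, region: str | None = None) -> Spectrum:
    """Read a two-column spectrum file.

    Rows may be comma- or whitespace-separated; ``#`` lines are comments,
    ``# key: value`` lines restore metadata.  Rows are sorted by wavenumber;
    duplicate wavenumbers raise.  ``region`` overrides any header tag.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in _META_FIELDS:
                        meta[key] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two numeric columns, got {line!r}"
                )
            try:
                wn, inten = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: malformed numeric value in {line!r}"
                ) from exc
            if not (math.isfinite(wn) and math.isfinite(inten)):
                raise SpectrumValidationError(
                    f"{path}:{lineno}: non-finite value in {line!r}"
                )
            rows.append((wn, inten))
    if len(rows) < 2:
        raise SpectrumValidationError(f"{path}: fewer than 2 data rows")
    rows.sort(key=lambda r: r[0])
    wn = np.array([r[0] for r in rows])
    if np.any(np.diff(wn) == 0):
        dup = wn[:-1][np.diff(wn) == 0][0]
        raise SpectrumValidationError(f"{path}: duplicate wavenumber {dup}")
    inten = np.array([r[1] for r in rows])

    frac = meta.get("fraction_pct")
    rep = meta.get("replicate")
    return Spectrum(
        wavenumbers=wn,
        intensities=inten,
        species=meta.get("species") or None,
        fraction_pct=None if frac in (None, "", "unknown") else float(frac),  # type: ignore[arg-type]
        region=region if region is not None else (meta.get("region") or None),  # type: ignore[arg-type]
        replicate=None if rep in (None, "") else int(rep),  # type: ignore[arg-type]
        baseline_corrected=str(meta.get("baseline_corrected", "")).lower() == "true",
        normalized=meta.get("normalized") or None,  # type: ignore[arg-type]
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write ``spectrum`` as two-column text with a ``# key: value`` header."""
    path = Path(path)
    lines = ["# oxiraman spectrum"]
    for key in _META_FIELDS:
        value = getattr(spectrum, key)
        if value in (None, False):
            continue
        lines.append(f"# {key}: {value}")
    for wn, inten in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{wn:.4f} {inten:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass(frozen=True)
class ManifestEntry:
    """One dataset file: path, species, nominal oxidized fraction, replicate."""

    path: Path
    species: str
    fraction_pct: float | None  # None = unknown
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.fraction_pct is not None and not (
            0.0 <= float(self.fraction_pct) <= 100.0
        ):
            raise ManifestError(
                f"fraction {self.fraction_pct} for {self.path} outside [0, 100]"
            )


@dataclass(frozen=True)
class DatasetManifest:
    """An ordered collection of :class:`ManifestEntry` with unique paths."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        paths = [str(e.path) for e in self.entries]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestError(f"duplicate paths in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load a manifest CSV (columns path, species, fraction_pct, replicate).

    Relative paths are resolved against the manifest's directory; all
    referenced files must exist.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"path", "species", "fraction_pct", "replicate"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ManifestError(f"{path}: missing manifest columns {sorted(missing_cols)}")
    base = path.parent
    entries = []
    for _, row in frame.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = (base / p).resolve()
        frac = row["fraction_pct"]
        entries.append(
            ManifestEntry(
                path=p,
                species=str(row["species"]),
                fraction_pct=None if pd.isna(frac) else float(frac),
                replicate=int(row["replicate"]),
            )
        )
    missing = [str(e.path) for e in entries if not e.path.exists()]
    if missing:
        raise ManifestError(f"{path}: missing referenced files: {missing}")
    return DatasetManifest(entries=tuple(entries))


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write a manifest CSV with paths relative to its location when possible."""
    path = Path(path)
    rows = []
    for e in manifest.entries:
        p = e.path
        try:
            p = p.resolve().relative_to(path.parent.resolve())
        except ValueError:
            pass
        rows.append(
            {
                "path": p.as_posix(),
                "species": e.species,
                "fraction_pct": "" if e.fraction_pct is None else e.fraction_pct,
                "replicate": e.replicate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
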