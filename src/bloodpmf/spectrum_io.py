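"""Centroided peak-list I/O and preprocessing filters.

Peak lists are plain-text tables (mMass-style ``.txt`` exports): whitespace-
or tab-delimited columns ``mz  intensity  [snr]`` with ``#`` comment lines.
The three filters — S/N threshold, exclusion-list removal, and acquisition-
window restriction — are idempotent, mutually commuting, and record
themselves in the peak list's processing history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Peak",
    "PeakList",
    "ExclusionList",
    "read_peaklist",
    "write_peaklist",
    "load_exclusion_list",
    "default_exclusion_list",
    "filter_snr",
    "apply_exclusion",
    "restrict_range",
    "preprocess",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    sample_id: str
    peaks: tuple[Peak, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz)))
        mzs = [p.mz for p in self.peaks]
        if len(set(mzs)) != len(mzs):
            raise ValueError("peak list contains duplicate m/z values after deduplication")

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak], step: str) -> "PeakList":
        return PeakList(
            sample_id=self.sample_id,
            peaks=tuple(peaks),
            metadata=dict(self.metadata),
            history=self.history + (step,),
        )


@dataclass(frozen=True)
class ExclusionList:
    """Known nuisance masses (matrix clusters, trypsin autolysis products)."""

    name: str
    entries: tuple[tuple[float, str], ...]
    tolerance_ppm: float = 15.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("exclusion tolerance must be positive")


def read_peaklist(path: str | Path, sample_id: str | None = None) -> PeakList:
    """Parse a text peak list; duplicate m/z rows are merged keeping the
    highest intensity."""
    path = Path(path)
    best: dict[float, Peak] = {}
    n_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected at least 2 columns")
            try:
                mz_val = float(fields[0])
                intensity = float(fields[1])
                snr = float(fields[2]) if len(fields) > 2 else None
            except ValueError:
                raise ValueError(f"{path}:{line_no}: non-numeric field") from None
            if intensity < 0:
                raise ValueError(f"{path}:{line_no}: negative intensity {intensity}")
            n_rows += 1
            peak = Peak(mz_val, intensity, snr)
            if mz_val not in best or intensity > best[mz_val].intensity:
                best[mz_val] = peak
    if n_rows == 0:
        raise ValueError(f"{path}: no parseable peak rows")
    return PeakList(
        sample_id=sample_id or path.stem,
        peaks=tuple(best.values()),
        metadata={"source_file": str(path)},
    )


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write with bit-stable 6-decimal m/z formatting."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {pl.sample_id}\n")
        fh.write("# mz intensity snr\n")
        for p in pl.peaks:
            snr = "" if p.snr is None else f"\t{p.snr:.2f}"
            fh.write(f"{p.mz:.6f}\t{p.intensity:.2f}{snr}\n")


def load_exclusion_list(path: str | Path) -> ExclusionList:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = tuple((float(e["mz"]), str(e.get("label", ""))) for e in doc["entries"])
    if not entries:
        raise ValueError(f"{path}: exclusion list has no entries")
    return ExclusionList(
        name=str(doc.get("name", Path(path).stem)),
        entries=entries,
        tolerance_ppm=float(doc.get("tolerance_ppm", 15.0)),
    )


def default_exclusion_list() -> ExclusionList:
    """Packaged CHCA-matrix / trypsin-autolysis defaults (plumbing values,
    fully overridable; not derived from any publication's own lists)."""
    from importlib.resources import files

    return load_exclusion_list(files("bloodpmf.data") / "exclusion_default.yml")


def filter_snr(pl: PeakList, threshold: float = 10.0) -> PeakList:
    """Keep peaks with S/N >= threshold (inclusive). Peaks with unknown S/N
    are retained and the list is flagged."""
    if threshold <= 0:
        raise ValueError("S/N threshold must be positive")
    kept = [p for p in pl.peaks if p.snr is None or p.snr >= threshold]
    out = pl.with_peaks(kept, f"filter_snr({threshold:g})")
    if any(p.snr is None for p in kept):
        md = dict(out.metadata)
        md["snr_unknown_retained"] = True
        out = replace(out, metadata=md)
    return out


def apply_exclusion(pl: PeakList, ex: ExclusionList) -> PeakList:
    """Remove peaks within ``ex.tolerance_ppm`` of any exclusion entry."""
    removed: list[str] = []
    kept = []
    for p in pl.peaks:
        hit = None
        for mz_val, label in ex.entries:
            if abs(p.mz - mz_val) / mz_val * 1e6 <= ex.tolerance_ppm:
                hit = label or f"{mz_val:.3f}"
                break
        if hit is None:
            kept.append(p)
        else:
            removed.append(f"{p.mz:.4f}->{hit}")
    out = pl.with_peaks(kept, f"apply_exclusion({ex.name})")
    if removed:
        md = dict(out.metadata)
        md.setdefault("excluded_peaks", []).extend(removed)  # type: ignore[union-attr]
        out = replace(out, metadata=md)
    return out


def restrict_range(pl: PeakList, lo: float = 600.0, hi: float = 2000.0) -> PeakList:
    """Keep peaks with lo <= m/z <= hi (inclusive bounds)."""
    if not lo < hi:
        raise ValueError(f"inverted m/z window [{lo}, {hi}]")
    kept = [p for p in pl.peaks if lo <= p.mz <= hi]
    return pl.with_peaks(kept, f"restrict_range({lo:g},{hi:g})")


def preprocess(
    pl: PeakList,
    snr_min: float = 10.0,
    exclusion: ExclusionList | None = None,
    lo: float = 600.0,
    hi: float = 2000.0,
) -> PeakList:
    """Standard pipeline: S/N threshold, exclusion removal, window restriction."""
    out = filter_snr(pl, snr_min)
    if exclusion is not None:
        out = apply_exclusion(out, exclusion)
    return restrict_range(out, lo, hi)
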