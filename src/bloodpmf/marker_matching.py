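"""Diagnostic marker panel and two-stage ppm matching (30 ppm candidate,
15 ppm confirmation).

Markers carry either a sequence-backed centre (MH+ computed from the
sequence), a literal centre m/z, or — for nominal-support markers whose
exact composition is unknown — only an integer nominal label, matched within
a +/-0.5 Th window. Nominal-support hits can raise the confidence of a
claim but never drive one.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .insilico_digest import TheoreticalTable
from .peptide_mass import (
    AminoAcidTable,
    IonSpec,
    Peptide,
    STANDARD_TABLE,
    mz,
    nominal_mz,
    ppm_error,
)
from .spectrum_io import Peak, PeakList

__all__ = [
    "Marker",
    "MarkerPanel",
    "MatchResult",
    "MarkerIds",
    "resolve_center",
    "match_marker",
    "match_panel",
    "annotate_against_table",
    "default_panel",
    "load_panel",
    "NOMINAL_WINDOW_TH",
    "CONFIRMED",
    "CANDIDATE",
    "UNMATCHED",
]

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
CANDIDATE = "candidate"
UNMATCHED = "unmatched"

ROLE_PRIMARY = "primary"
ROLE_SUPPORTING = "supporting"
ROLE_NOMINAL = "nominal-support"

#: Matching half-window for nominal-support markers with no exact centre.
NOMINAL_WINDOW_TH = 0.5


class MarkerIds:
    """Well-known marker identifiers referenced by the decision tree."""

    HBB_SHARED = "hbb-llvvypwtqr"
    HBA_SHARED = "hba-vgghaaeygaealer"
    HUMAN_HBB_932 = "human-hbb-932"
    HUMAN_EPB42_1087 = "human-epb42-1087"
    HUMAN_HPT_1378 = "human-hpt-1378"
    CHICKEN_GAPDH = "chicken-gapdh-1750"
    CHICKEN_APOA1_1580 = "chicken-apoa1-1580"
    MAMMAL_GAPDH = "mammal-gapdh-1764"
    BOVINE_MYO_1593 = "bovine-myoglobin-1593"
    BOVINE_MYO_1670 = "bovine-myoglobin-1670"
    PORCINE_MYO_649 = "porcine-myoglobin-649"
    SEM1_1715 = "sem1-1715"
    SEM_1445 = "sem-1445"
    SEM2_1555 = "sem2-1555"
    SEM_1501 = "sem-1501"
    SEM1_1801 = "sem1-1801"
    SEM2_1883 = "sem2-1883"

    CHICKEN_GAPDH_SUPPORTS = (
        "chicken-gapdh-795",
        "chicken-gapdh-805",
        "chicken-gapdh-1033",
        "chicken-gapdh-1359",
        "chicken-gapdh-1646",
    )


@dataclass(frozen=True)
class Marker:
    id: str
    protein: str
    biofluid: str  # "blood" | "semen"
    species_set: frozenset[str]
    role: str = ROLE_PRIMARY
    sequence: str | None = None
    literal_mz: float | None = None
    nominal: int | None = None
    accession: str = ""

    def __post_init__(self) -> None:
        if self.role not in (ROLE_PRIMARY, ROLE_SUPPORTING, ROLE_NOMINAL):
            raise ValueError(f"{self.id}: unknown role {self.role!r}")
        if self.sequence is None and self.literal_mz is None and self.nominal is None:
            raise ValueError(f"{self.id}: marker needs a sequence, literal m/z or nominal label")


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[Marker, ...]
    strategy_version: str = "refined"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")

    def __iter__(self):
        return iter(self.markers)

    def get(self, marker_id: str) -> Marker | None:
        for m in self.markers:
            if m.id == marker_id:
                return m
        return None


@dataclass(frozen=True)
class MatchResult:
    marker_id: str
    matched_peak: Peak | None
    ppm: float | None
    stage: str

    @property
    def confirmed(self) -> bool:
        return self.stage == CONFIRMED


def resolve_center(m: Marker, t: AminoAcidTable = STANDARD_TABLE) -> float | None:
    """Exact matching centre: sequence-backed MH+ takes precedence over a
    literal value; nominal-only markers resolve to None (window matching)."""
    if m.sequence is not None:
        return mz(Peptide(m.sequence), IonSpec(charge=1), t)
    if m.literal_mz is not None:
        return m.literal_mz
    logger.info("marker %s has no exact centre; window matching on nominal %s", m.id, m.nominal)
    return None


def marker_nominal(m: Marker, t: AminoAcidTable = STANDARD_TABLE) -> int:
    if m.nominal is not None:
        return m.nominal
    center = resolve_center(m, t)
    assert center is not None
    return nominal_mz(center)


def _best_peak(
    candidates: Sequence[tuple[Peak, float]]
) -> tuple[Peak, float] | None:
    """Smallest |ppm|; ties broken toward higher intensity, then lower m/z."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (abs(c[1]), -c[0].intensity, c[0].mz))


def match_marker(
    pl: PeakList,
    m: Marker,
    candidate_ppm: float = 30.0,
    confirm_ppm: float = 15.0,
    t: AminoAcidTable = STANDARD_TABLE,
) -> MatchResult:
    if not 0 < confirm_ppm <= candidate_ppm:
        raise ValueError("require 0 < confirm_ppm <= candidate_ppm")
    center = resolve_center(m, t)
    if center is None:
        # Nominal-support: +/-0.5 Th window around the integer label; the ppm
        # error is undefined because the true centre is unknown.
        assert m.nominal is not None
        hits = [p for p in pl.peaks if abs(p.mz - m.nominal) <= NOMINAL_WINDOW_TH]
        if not hits:
            return MatchResult(m.id, None, None, UNMATCHED)
        best = max(hits, key=lambda p: p.intensity)
        return MatchResult(m.id, best, None, CONFIRMED)
    candidates = []
    for p in pl.peaks:
        err = ppm_error(p.mz, center)
        if abs(err) <= candidate_ppm:
            candidates.append((p, err))
    best = _best_peak(candidates)
    if best is None:
        return MatchResult(m.id, None, None, UNMATCHED)
    peak, err = best
    stage = CONFIRMED if abs(err) <= confirm_ppm else CANDIDATE
    return MatchResult(m.id, peak, err, stage)


def match_panel(
    pl: PeakList,
    panel: MarkerPanel,
    candidate_ppm: float = 30.0,
    confirm_ppm: float = 15.0,
    t: AminoAcidTable = STANDARD_TABLE,
) -> list[MatchResult]:
    return [match_marker(pl, m, candidate_ppm, confirm_ppm, t) for m in panel]


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    entry_index: int
    ppm: float
    stage: str
    ambiguous: bool = False


def annotate_against_table(
    pl: PeakList,
    table: TheoreticalTable,
    candidate_ppm: float = 30.0,
    confirm_ppm: float = 15.0,
) -> list[PeakAnnotation]:
    """Annotate each peak with every table entry within the candidate
    tolerance, via binary search over the m/z-sorted table."""
    if not 0 < confirm_ppm <= candidate_ppm:
        raise ValueError("require 0 < confirm_ppm <= candidate_ppm")
    mzs = [e.mz for e in table.entries]
    out: list[PeakAnnotation] = []
    for p in pl.peaks:
        half = p.mz * candidate_ppm / 1e6
        lo = bisect.bisect_left(mzs, p.mz - half)
        hi = bisect.bisect_right(mzs, p.mz + half)
        hits = []
        for idx in range(lo, hi):
            err = ppm_error(p.mz, mzs[idx])
            if abs(err) <= candidate_ppm:
                hits.append((idx, err))
        ambiguous = sum(1 for _, err in hits if abs(err) <= confirm_ppm) > 1
        for idx, err in hits:
            stage = CONFIRMED if abs(err) <= confirm_ppm else CANDIDATE
            out.append(PeakAnnotation(p, idx, err, stage, ambiguous))
    return out


_HUMAN_BOV_PORC = frozenset({"human", "bovine", "porcine"})


def default_panel(version: str = "refined") -> MarkerPanel:
    """The built-in marker panel for blood/semen identification."""
    human_markers = (
        Marker(MarkerIds.HBB_SHARED, "haemoglobin beta", "blood", _HUMAN_BOV_PORC,
               ROLE_PRIMARY, sequence="LLVVYPWTQR", accession="P68871"),
        Marker(MarkerIds.HBA_SHARED, "haemoglobin alpha", "blood",
               frozenset({"human", "bovine"}), ROLE_PRIMARY,
               sequence="VGGHAAEYGAEALER", accession="P69905"),
        Marker(MarkerIds.HUMAN_HBB_932, "haemoglobin beta", "blood",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=932.520),
        Marker(MarkerIds.HUMAN_EPB42_1087, "erythrocyte membrane protein band 4.2",
               "blood", frozenset({"human"}), ROLE_SUPPORTING,
               literal_mz=1087.553, accession="P16452"),
        Marker(MarkerIds.HUMAN_HPT_1378, "haptoglobin", "blood",
               frozenset({"human"}), ROLE_SUPPORTING,
               literal_mz=1378.694, accession="P00738"),
    )
    if version == "initial":
        return MarkerPanel(markers=human_markers, strategy_version="initial")
    if version != "refined":
        raise ValueError(f"unknown panel version {version!r}")
    chicken_supports = tuple(
        Marker(mid, "GAPDH", "blood", frozenset({"chicken"}), ROLE_NOMINAL,
               nominal=int(mid.rsplit("-", 1)[1]), accession="P00356")
        for mid in MarkerIds.CHICKEN_GAPDH_SUPPORTS
    )
    markers = human_markers + (
        Marker(MarkerIds.CHICKEN_GAPDH, "GAPDH", "blood", frozenset({"chicken"}),
               ROLE_PRIMARY, sequence="LVSWYDNEFGYSNR", accession="P00356"),
    ) + chicken_supports + (
        Marker(MarkerIds.CHICKEN_APOA1_1580, "apolipoprotein A1", "blood",
               frozenset({"chicken"}), ROLE_SUPPORTING,
               literal_mz=1580.817, accession="P08250"),
        Marker(MarkerIds.MAMMAL_GAPDH, "GAPDH", "blood",
               frozenset({"bovine", "porcine"}), ROLE_PRIMARY,
               sequence="LISWYDNEFGYSNR", accession="P00355"),
        Marker(MarkerIds.BOVINE_MYO_1593, "myoglobin", "blood",
               frozenset({"bovine", "porcine"}), ROLE_PRIMARY,
               sequence="VEADVAGHGQEVLIR", accession="P02192"),
        Marker(MarkerIds.BOVINE_MYO_1670, "myoglobin", "blood",
               frozenset({"bovine"}), ROLE_SUPPORTING, literal_mz=1669.837,
               accession="P02192"),
        Marker(MarkerIds.PORCINE_MYO_649, "myoglobin", "blood",
               frozenset({"porcine"}), ROLE_NOMINAL, nominal=649,
               accession="P02189"),
        Marker(MarkerIds.SEM1_1715, "semenogelin 1", "semen",
               frozenset({"human"}), ROLE_PRIMARY,
               sequence="GLRPSEFSQFPHGQK", accession="P04279"),
        Marker(MarkerIds.SEM_1445, "semenogelin 1/2", "semen",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=1444.764),
        Marker(MarkerIds.SEM2_1555, "semenogelin 2", "semen",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=1554.779),
        Marker(MarkerIds.SEM_1501, "semenogelin 1", "semen",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=1501.744),
        Marker(MarkerIds.SEM1_1801, "semenogelin 1", "semen",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=1801.918),
        Marker(MarkerIds.SEM2_1883, "semenogelin 2", "semen",
               frozenset({"human"}), ROLE_SUPPORTING, literal_mz=1883.936),
    )
    return MarkerPanel(markers=markers, strategy_version="refined")


def load_panel(path: str | Path) -> MarkerPanel:
    """Load a panel from YAML config (id, sequence or literal m/z or nominal,
    protein, biofluid, species, role)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    markers = []
    for item in doc["markers"]:
        markers.append(
            Marker(
                id=str(item["id"]),
                protein=str(item.get("protein", "")),
                biofluid=str(item.get("biofluid", "blood")),
                species_set=frozenset(item.get("species", [])),
                role=str(item.get("role", ROLE_PRIMARY)),
                sequence=item.get("sequence"),
                literal_mz=(float(item["literal_mz"]) if "literal_mz" in item else None),
                nominal=(int(item["nominal"]) if "nominal" in item else None),
                accession=str(item.get("accession", "")),
            )
        )
    return MarkerPanel(
        markers=tuple(markers),
        strategy_version=str(doc.get("strategy_version", "refined")),
    )
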