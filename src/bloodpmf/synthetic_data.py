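"""Synthetic centroided peak lists and machine-readable blind-cohort fixtures.

``simulate_peaklist`` places marker peaks for a sample's truth class at the
panel centres with Gaussian ppm jitter, adds uniform background peaks (kept
clear of every marker window), samples S/N values, and supports per-marker
dropout and force-present/absent overrides. Cohort fixtures encode the
blind-sample inventories (sample ids, truth classes, enhancement tags and
minimal marker presence/absence patterns) as packaged JSON so cohort-level
statistics are reproducible offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np

from .marker_matching import (
    Marker,
    MarkerIds,
    MarkerPanel,
    ROLE_PRIMARY,
    default_panel,
    resolve_center,
)
from .spectrum_io import Peak, PeakList, default_exclusion_list

__all__ = [
    "SampleSpec",
    "SimConfig",
    "CohortFixture",
    "TRUTH_CLASSES",
    "BLOOD_TRUTHS",
    "CLASS_MARKERS",
    "simulate_peaklist",
    "load_fixture",
    "cohort_peaklists",
]

TRUTH_CLASSES = (
    "human_blood",
    "bovine_blood",
    "porcine_blood",
    "chicken_blood",
    "semen",
    "saliva",
    "sweat",
    "non_biofluid",
    "blank",
)

BLOOD_TRUTHS = frozenset(
    {"human_blood", "bovine_blood", "porcine_blood", "chicken_blood"}
)

ENHANCEMENTS = ("none", "AB-1", "AY-7", "LCV")

#: Marker ids emitted by default for each truth class. These follow the
#: empirical blind-sample profiles (animal blind samples carry GAPDH and
#: myoglobin rather than the haemoglobin signals seen in intravenous blood).
CLASS_MARKERS: Mapping[str, tuple[str, ...]] = {
    "human_blood": (
        MarkerIds.HBB_SHARED,
        MarkerIds.HBA_SHARED,
        MarkerIds.HUMAN_HBB_932,
        MarkerIds.HUMAN_EPB42_1087,
        MarkerIds.HUMAN_HPT_1378,
    ),
    "chicken_blood": (
        MarkerIds.CHICKEN_GAPDH,
        *MarkerIds.CHICKEN_GAPDH_SUPPORTS,
        MarkerIds.CHICKEN_APOA1_1580,
    ),
    "bovine_blood": (
        MarkerIds.MAMMAL_GAPDH,
        MarkerIds.BOVINE_MYO_1593,
        MarkerIds.BOVINE_MYO_1670,
    ),
    "porcine_blood": (
        MarkerIds.MAMMAL_GAPDH,
        MarkerIds.PORCINE_MYO_649,
    ),
    "semen": (
        MarkerIds.SEM1_1715,
        MarkerIds.SEM_1445,
        MarkerIds.SEM2_1555,
        MarkerIds.SEM_1501,
        MarkerIds.SEM1_1801,
        MarkerIds.SEM2_1883,
    ),
    "saliva": (),
    "sweat": (),
    "non_biofluid": (),
    "blank": (),
}


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    truth: str
    enhancement: str = "none"
    marker_overrides: Mapping[str, str] = field(default_factory=dict)
    trace: bool = False
    comment: str = ""

    def __post_init__(self) -> None:
        if self.truth not in TRUTH_CLASSES:
            raise ValueError(f"{self.sample_id}: unknown truth class {self.truth!r}")
        if self.enhancement not in ENHANCEMENTS:
            raise ValueError(f"{self.sample_id}: unknown enhancement {self.enhancement!r}")
        for mid, state in self.marker_overrides.items():
            if state not in ("present", "absent"):
                raise ValueError(f"{self.sample_id}: override for {mid} must be present/absent")
        if self.trace and any(v == "present" for v in self.marker_overrides.values()):
            raise ValueError(f"{self.sample_id}: trace samples cannot force markers present")


@dataclass(frozen=True)
class SimConfig:
    ppm_jitter_sd: float = 3.0
    background_peaks: int = 40
    snr_lognormal_mu: float = 2.8
    snr_lognormal_sigma: float = 0.9
    snr_floor: float = 3.0
    marker_snr_min: float = 15.0
    dropout_prob_supporting: float = 0.3
    dropout_prob_primary: float = 0.0
    include_exclusion_peaks: bool = False
    mz_min: float = 600.0
    mz_max: float = 2000.0

    def __post_init__(self) -> None:
        if self.ppm_jitter_sd < 0:
            raise ValueError("ppm_jitter_sd must be >= 0")
        for p in (self.dropout_prob_supporting, self.dropout_prob_primary):
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortFixture:
    name: str
    samples: tuple[SampleSpec, ...]
    expected_claims: Mapping[str, Mapping[str, str]]
    subsets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def subset(self, name: str) -> tuple[SampleSpec, ...]:
        ids = set(self.subsets[name])
        return tuple(s for s in self.samples if s.sample_id in ids)


def _marker_center(m: Marker) -> float:
    center = resolve_center(m)
    if center is None:
        assert m.nominal is not None
        return float(m.nominal)
    return center


def _protected_windows(panel: MarkerPanel) -> list[tuple[float, float]]:
    """m/z intervals background peaks must avoid: the candidate ppm window
    around each exact centre and the nominal window (padded) around each
    window-matched marker."""
    out = []
    for m in panel:
        center = resolve_center(m)
        if center is not None:
            half = max(center * 30.0 / 1e6, 0.06)
            out.append((center - half, center + half))
        if m.nominal is not None or center is None:
            nom = float(m.nominal) if m.nominal is not None else center
            out.append((nom - 0.6, nom + 0.6))
    return out


def simulate_peaklist(
    spec: SampleSpec,
    cfg: SimConfig,
    panel: MarkerPanel,
    rng: np.random.Generator,
) -> PeakList:
    """One synthetic centroided peak list; deterministic for a fixed rng state.

    Dropout decisions use one uniform draw per panel marker in panel order,
    so raising a dropout probability can only remove marker peaks (the
    remaining random stream is unaffected).
    """
    dropout_u = {m.id: rng.random() for m in panel}
    jitter = {m.id: rng.normal(0.0, 1.0) for m in panel}

    class_ids = set(CLASS_MARKERS[spec.truth])
    present: set[str] = set()
    if not spec.trace:
        for m in panel:
            state = spec.marker_overrides.get(m.id)
            if state == "present":
                present.add(m.id)
                continue
            if state == "absent" or m.id not in class_ids:
                continue
            p_drop = (
                cfg.dropout_prob_primary
                if m.role == ROLE_PRIMARY
                else cfg.dropout_prob_supporting
            )
            if dropout_u[m.id] >= p_drop:
                present.add(m.id)

    peaks: dict[float, Peak] = {}
    for m in panel:
        if m.id not in present:
            continue
        center = _marker_center(m)
        mz_val = center * (1.0 + cfg.ppm_jitter_sd * jitter[m.id] / 1e6)
        intensity = float(rng.lognormal(9.0, 0.7))
        snr = max(cfg.marker_snr_min, float(rng.lognormal(3.5, 0.6)))
        if cfg.mz_min <= mz_val <= cfg.mz_max:
            peaks[mz_val] = Peak(mz_val, intensity, snr)

    windows = _protected_windows(panel)
    for _ in range(cfg.background_peaks):
        for _attempt in range(1000):
            mz_val = float(rng.uniform(cfg.mz_min, cfg.mz_max))
            if not any(lo <= mz_val <= hi for lo, hi in windows):
                break
        else:  # pragma: no cover - window coverage is tiny
            raise RuntimeError("could not place background peak clear of marker windows")
        intensity = float(rng.lognormal(7.0, 1.0))
        snr = max(cfg.snr_floor, float(rng.lognormal(cfg.snr_lognormal_mu, cfg.snr_lognormal_sigma)))
        if mz_val not in peaks:
            peaks[mz_val] = Peak(mz_val, intensity, snr)

    if cfg.include_exclusion_peaks:
        for mz_val, label in default_exclusion_list().entries:
            if cfg.mz_min <= mz_val <= cfg.mz_max and mz_val not in peaks:
                peaks[mz_val] = Peak(mz_val, float(rng.lognormal(8.0, 0.5)), 25.0)

    return PeakList(
        sample_id=spec.sample_id,
        peaks=tuple(peaks.values()),
        metadata={
            "synthetic": True,
            "enhancement": spec.enhancement,
            "truth": spec.truth,
        },
    )


def load_fixture(name: str) -> CohortFixture:
    """Load a packaged blind-cohort fixture: ``table1`` (40 samples, initial
    strategy), ``table5`` (56, post-refinement) or ``table6`` (13, final
    validation)."""
    expected_n = {"table1": 40, "table5": 56, "table6": 13}
    if name not in expected_n:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(expected_n)}")
    doc = json.loads((files("bloodpmf.data") / "fixtures" / f"{name}.json").read_text())
    samples = tuple(
        SampleSpec(
            sample_id=s["sample_id"],
            truth=s["truth"],
            enhancement=s.get("enhancement", "none"),
            marker_overrides=s.get("marker_overrides", {}),
            trace=s.get("trace", False),
            comment=s.get("comment", ""),
        )
        for s in doc["samples"]
    )
    if len(samples) != expected_n[name]:
        raise ValueError(
            f"{name}: fixture has {len(samples)} samples, expected {expected_n[name]}"
        )
    expected_claims = {s["sample_id"]: s["expected_claim"] for s in doc["samples"]}
    subsets = {k: tuple(v) for k, v in doc.get("subsets", {}).items()}
    return CohortFixture(name=name, samples=samples, expected_claims=expected_claims, subsets=subsets)


def cohort_peaklists(
    fixture: CohortFixture,
    cfg: SimConfig,
    panel: MarkerPanel | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[PeakList, str, Mapping[str, str]]]:
    """Simulate one peak list per fixture sample. Returns
    ``(peak_list, truth, expected_claim)`` triples in fixture order."""
    panel = panel if panel is not None else default_panel("refined")
    rng = rng if rng is not None else np.random.default_rng(0)
    children = rng.spawn(len(fixture.samples))
    out = []
    for spec, child in zip(fixture.samples, children):
        pl = simulate_peaklist(spec, cfg, panel, child)
        out.append((pl, spec.truth, fixture.expected_claims[spec.sample_id]))
    return out
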