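"""Rule-based decision tree mapping confirmed marker matches to identity
claims across identification levels I-V.

Level I: blood present? Level II: human vs animal. Level III: animal
species. Level IV/V: other biofluid (semen). The refined strategy evaluates
eight ordered, mutually exclusive branches; the initial (pre-refinement)
strategy only knows the human haemoglobin pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .marker_matching import (
    MarkerIds,
    MarkerPanel,
    MatchResult,
    match_panel,
)
from .peptide_mass import AminoAcidTable, STANDARD_TABLE
from .spectrum_io import PeakList

__all__ = ["StrategyConfig", "Claim", "classify", "classify_initial", "explain"]

YES = "yes"
NO = "no"
INCONCLUSIVE = "inconclusive"
NA = "n/a"

HUMAN = "human"
ANIMAL = "animal"
CHICKEN = "chicken"
BOVINE = "bovine"
PORCINE = "porcine"

SEMEN = "semen"
NONE_DETECTED = "none-detected"


@dataclass(frozen=True)
class StrategyConfig:
    candidate_ppm: float = 30.0
    confirm_ppm: float = 15.0
    snr_min: float = 10.0
    version: str = "refined"  # "refined" | "initial"
    bovine_from_myoglobin_alone: bool = False

    def __post_init__(self) -> None:
        if self.version not in ("refined", "initial"):
            raise ValueError(f"unknown strategy version {self.version!r}")
        if not 0 < self.confirm_ppm <= self.candidate_ppm:
            raise ValueError("require 0 < confirm_ppm <= candidate_ppm")


@dataclass(frozen=True)
class Claim:
    level_i_blood: str  # yes | no | inconclusive
    level_ii_provenance: str  # human | animal | n/a | inconclusive
    level_iii_species: str  # chicken | bovine | porcine | inconclusive | n/a
    level_iv_other_biofluid: str  # semen | none-detected
    branch: int
    confidence_notes: tuple[str, ...] = ()
    evidence: tuple[MatchResult, ...] = ()

    def __post_init__(self) -> None:
        if self.level_ii_provenance != NA and self.level_i_blood != YES:
            raise ValueError("level II may only be set when level I is 'yes'")
        if self.level_iii_species != NA and self.level_ii_provenance != ANIMAL:
            raise ValueError("level III may only be set when level II is 'animal'")


def _require_preprocessed(pl: PeakList) -> None:
    tags = {h.split("(")[0] for h in pl.history}
    missing = {"filter_snr", "restrict_range"} - tags
    if missing:
        raise ValueError(
            f"peak list {pl.sample_id!r} is not preprocessed; missing steps: {sorted(missing)}"
        )


def _evidence_map(results: Sequence[MatchResult]) -> Mapping[str, MatchResult]:
    return {r.marker_id: r for r in results}


def classify(
    pl: PeakList,
    panel: MarkerPanel,
    cfg: StrategyConfig = StrategyConfig(),
    t: AminoAcidTable = STANDARD_TABLE,
) -> Claim:
    """Apply the refined (or initial, per cfg) decision tree to a
    preprocessed peak list."""
    if cfg.version == "initial":
        return classify_initial(pl, panel, cfg, t)
    _require_preprocessed(pl)
    results = match_panel(pl, panel, cfg.candidate_ppm, cfg.confirm_ppm, t)
    ev = _evidence_map(results)

    def hit(marker_id: str) -> bool:
        r = ev.get(marker_id)
        return r is not None and r.confirmed

    notes: list[str] = []
    evidence = tuple(results)

    semen_hit = hit(MarkerIds.SEM1_1715) or (
        hit(MarkerIds.SEM_1445) and hit(MarkerIds.SEM2_1555)
    )

    # Branch 1 — human blood: both shared haemoglobin peptides confirmed.
    if hit(MarkerIds.HBB_SHARED) and hit(MarkerIds.HBA_SHARED):
        notes.append(
            "caveat: both haemoglobin peptides are shared with bovine; a false "
            "human-blood positive cannot be excluded"
        )
        for sup in (MarkerIds.HUMAN_HBB_932, MarkerIds.HUMAN_EPB42_1087, MarkerIds.HUMAN_HPT_1378):
            if hit(sup):
                notes.append(f"human support confirmed: {sup}")
        if semen_hit:
            notes.append(
                "possible blood/semen co-presence; confirmatory MS/MS analyses recommended"
            )
        return Claim(YES, HUMAN, NA, SEMEN if semen_hit else NONE_DETECTED,
                     branch=1, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 2 — chicken blood via GAPDH.
    if hit(MarkerIds.CHICKEN_GAPDH):
        for sup in MarkerIds.CHICKEN_GAPDH_SUPPORTS + (MarkerIds.CHICKEN_APOA1_1580,):
            if hit(sup):
                notes.append(f"chicken support present: {sup}")
        return Claim(YES, ANIMAL, CHICKEN, NONE_DETECTED,
                     branch=2, confidence_notes=tuple(notes), evidence=evidence)

    mammal_gapdh = hit(MarkerIds.MAMMAL_GAPDH)
    myo_1593 = hit(MarkerIds.BOVINE_MYO_1593)
    myo_1670 = hit(MarkerIds.BOVINE_MYO_1670)

    # Branch 3 — bovine: mammalian GAPDH plus a myoglobin signal.
    if mammal_gapdh and (myo_1593 or myo_1670):
        return Claim(YES, ANIMAL, BOVINE, NONE_DETECTED,
                     branch=3, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 4 — porcine: mammalian GAPDH without myoglobin.
    if mammal_gapdh:
        if hit(MarkerIds.PORCINE_MYO_649):
            notes.append("porcine-support-649 present: confidence raised")
        notes.append("wild boar is reported as porcine (sus scrofa unresolved)")
        return Claim(YES, ANIMAL, PORCINE, NONE_DETECTED,
                     branch=4, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 5 — myoglobin without mammalian GAPDH.
    if myo_1593 or myo_1670:
        species = BOVINE if (cfg.bovine_from_myoglobin_alone and myo_1593) else INCONCLUSIVE
        if species == INCONCLUSIVE:
            notes.append("myoglobin detected without mammalian GAPDH; species not attributed")
        return Claim(YES, ANIMAL, species, NONE_DETECTED,
                     branch=5, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 6 — semen without blood.
    if semen_hit:
        for sup in (MarkerIds.SEM_1501, MarkerIds.SEM1_1801, MarkerIds.SEM2_1883):
            if hit(sup):
                notes.append(f"semen support present: {sup}")
        return Claim(NO, NA, NA, SEMEN,
                     branch=6, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 7 — a single haemoglobin signal: inconclusive, needs MS/MS.
    if hit(MarkerIds.HBB_SHARED) != hit(MarkerIds.HBA_SHARED):
        notes.append(
            "only one haemoglobin signal confirmed; MS/MS confirmation recommended"
        )
        return Claim(INCONCLUSIVE, NA, NA, NONE_DETECTED,
                     branch=7, confidence_notes=tuple(notes), evidence=evidence)

    # Branch 8 — nothing diagnostic.
    return Claim(NO, NA, NA, NONE_DETECTED,
                 branch=8, confidence_notes=tuple(notes), evidence=evidence)


def classify_initial(
    pl: PeakList,
    panel: MarkerPanel,
    cfg: StrategyConfig = StrategyConfig(version="initial"),
    t: AminoAcidTable = STANDARD_TABLE,
) -> Claim:
    """Pre-refinement strategy: only the human haemoglobin pair is
    diagnostic; animal and semen markers are ignored."""
    _require_preprocessed(pl)
    results = match_panel(pl, panel, cfg.candidate_ppm, cfg.confirm_ppm, t)
    ev = _evidence_map(results)

    def hit(marker_id: str) -> bool:
        r = ev.get(marker_id)
        return r is not None and r.confirmed

    notes: list[str] = []
    evidence = tuple(results)
    hbb, hba = hit(MarkerIds.HBB_SHARED), hit(MarkerIds.HBA_SHARED)
    for sup in (MarkerIds.HUMAN_HBB_932, MarkerIds.HUMAN_EPB42_1087, MarkerIds.HUMAN_HPT_1378):
        if hit(sup):
            notes.append(f"human support confirmed: {sup}")
    if hbb and hba:
        return Claim(YES, HUMAN, NA, NONE_DETECTED,
                     branch=1, confidence_notes=tuple(notes), evidence=evidence)
    if hbb != hba:
        notes.append("only one haemoglobin signal confirmed; MS/MS confirmation recommended")
        return Claim(INCONCLUSIVE, NA, NA, NONE_DETECTED,
                     branch=7, confidence_notes=tuple(notes), evidence=evidence)
    return Claim(NO, NA, NA, NONE_DETECTED,
                 branch=8, confidence_notes=tuple(notes), evidence=evidence)


def explain(claim: Claim) -> str:
    """Human-readable narrative of the claim and its evidence."""
    lines = [
        f"Decision branch fired: {claim.branch}",
        f"Level I   (blood present):     {claim.level_i_blood}",
        f"Level II  (provenance):        {claim.level_ii_provenance}",
        f"Level III (animal species):    {claim.level_iii_species}",
        f"Level IV  (other biofluid):    {claim.level_iv_other_biofluid}",
    ]
    if claim.level_i_blood == NO and claim.level_iv_other_biofluid == NONE_DETECTED:
        lines.append("No blood detected; no other biofluid markers confirmed.")
    if claim.confidence_notes:
        lines.append("Notes:")
        lines.extend(f"  - {n}" for n in claim.confidence_notes)
    if claim.evidence:
        lines.append("Marker evidence:")
        for r in claim.evidence:
            if r.matched_peak is None:
                lines.append(f"  {r.marker_id}: unmatched")
            elif r.ppm is None:
                lines.append(
                    f"  {r.marker_id}: window hit at m/z {r.matched_peak.mz:.3f} ({r.stage})"
                )
            else:
                lines.append(
                    f"  {r.marker_id}: m/z {r.matched_peak.mz:.3f} ({r.ppm:+.1f} ppm, {r.stage})"
                )
    return "\n".join(lines)
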