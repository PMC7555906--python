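"""In-silico tryptic digestion and cross-species peptide specificity tables.

Digestion follows the Keil rule (cleavage C-terminal to K/R, suppressed
before proline) with configurable missed cleavages and variable methionine
oxidation, producing singly protonated monoisotopic m/z tables restricted to
an acquisition window. Specificity annotation marks each peptide either as
proteotypic to one species or shared, by exact sequence identity across the
species panel (modification state ignored).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .peptide_mass import AminoAcidTable, IonSpec, Peptide, STANDARD_TABLE, mz

__all__ = [
    "ProteinRecord",
    "DigestParams",
    "PeptideEntry",
    "TheoreticalTable",
    "read_fasta",
    "cleavage_sites",
    "enumerate_peptides",
    "annotate_specificity",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_OS_FIELD = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")

#: Peptides with more methionines than this enumerate only the unmodified
#: and fully oxidised states (combinatorial cap).
MAX_ENUMERATED_METHIONINES = 4

PROTEOTYPIC = "proteotypic"
SHARED = "shared"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    species: str
    protein_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residue codes {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings mirroring a PeptideMass-style configuration."""

    max_missed_cleavages: int = 2
    variable_met_oxidation: bool = True
    mz_min: float = 600.0
    mz_max: float = 2000.0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not self.mz_min < self.mz_max:
            raise ValueError(f"mz_min must be < mz_max ({self.mz_min} >= {self.mz_max})")


@dataclass(frozen=True)
class PeptideEntry:
    accession: str
    species: str
    peptide: Peptide
    missed_cleavages: int
    mz: float
    specificity: str = PROTEOTYPIC
    shared_species: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TheoreticalTable:
    entries: tuple[PeptideEntry, ...]
    params: DigestParams
    panel_species: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(sorted(self.entries, key=lambda e: e.mz)))
        seen = set()
        for e in self.entries:
            key = (e.accession, e.peptide.sequence, e.peptide.oxidized_positions, e.missed_cleavages)
            if key in seen:
                raise ValueError(f"duplicate table row for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)


def _parse_header(header: str, species_map: Mapping[str, str] | None) -> tuple[str, str, str]:
    """Return (accession, species, protein_name) from a FASTA description."""
    m = _UNIPROT_HEADER.match(header)
    if m:
        accession, name = m.group("acc"), m.group("name")
    else:
        token = header.split()[0] if header.split() else ""
        if not token:
            raise ValueError("malformed FASTA header: empty identifier")
        accession, name = token, token
    species = ""
    os_match = _OS_FIELD.search(header)
    if os_match:
        species = os_match.group(1).strip()
    if species_map and accession in species_map:
        species = species_map[accession]
    return accession, species, name


def read_fasta(path: str | Path, species_map: Mapping[str, str] | None = None) -> list[ProteinRecord]:
    """Read protein records, rejecting sequences with non-standard residues.

    ``species_map`` maps accession -> taxon label and overrides any ``OS=``
    field found in the header.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        accession, species, name = _parse_header(rec.description, species_map)
        sequence = str(rec.seq).upper()
        bad = set(sequence) - _VALID_RESIDUES
        if bad:
            line_no = _find_offending_line(path, bad)
            raise ValueError(
                f"{path}:{line_no}: record {accession} contains non-residue characters {sorted(bad)}"
            )
        out.append(ProteinRecord(accession, species, name, sequence))
    return out


def _find_offending_line(path: Path, bad_chars: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return i
    return 0


def cleavage_sites(sequence: str) -> list[int]:
    """Positions (residue counts from the N-terminus) after which trypsin cuts.

    A position ``i`` means a cut between ``sequence[i-1]`` and ``sequence[i]``;
    the C-terminus is never reported as a site.
    """
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def _oxidation_states(sequence: str, enabled: bool) -> list[frozenset[int]]:
    if not enabled:
        return [frozenset()]
    met_positions = [i + 1 for i, c in enumerate(sequence) if c == "M"]
    if not met_positions:
        return [frozenset()]
    if len(met_positions) > MAX_ENUMERATED_METHIONINES:
        logger.warning(
            "peptide with %d methionines: enumerating only 0- and fully-oxidised states",
            len(met_positions),
        )
        return [frozenset(), frozenset(met_positions)]
    states = []
    for k in range(len(met_positions) + 1):
        states.extend(frozenset(c) for c in combinations(met_positions, k))
    return states


def enumerate_peptides(
    record: ProteinRecord,
    params: DigestParams = DigestParams(),
    t: AminoAcidTable = STANDARD_TABLE,
) -> list[PeptideEntry]:
    """All tryptic products with 0..max missed cleavages and oxidation variants.

    Emits one entry per distinct (sequence, missed-cleavage count, oxidation
    state) triple whose MH+ lies within [mz_min, mz_max].
    """
    bounds = [0] + cleavage_sites(record.sequence) + [len(record.sequence)]
    ion = IonSpec(charge=params.charge)
    seen: set[tuple] = set()
    out: list[PeptideEntry] = []
    for i in range(len(bounds) - 1):
        for mc in range(params.max_missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            subseq = record.sequence[bounds[i] : bounds[j]]
            for ox in _oxidation_states(subseq, params.variable_met_oxidation):
                key = (subseq, mc, ox)
                if key in seen:
                    continue
                seen.add(key)
                peptide = Peptide(subseq, ox)
                value = mz(peptide, ion, t)
                if params.mz_min <= value <= params.mz_max:
                    out.append(
                        PeptideEntry(
                            accession=record.accession,
                            species=record.species,
                            peptide=peptide,
                            missed_cleavages=mc,
                            mz=value,
                        )
                    )
    return out


def annotate_specificity(
    per_species: Mapping[str, Sequence[PeptideEntry]],
    params: DigestParams = DigestParams(),
) -> TheoreticalTable:
    """Mark every entry proteotypic or shared across the species panel.

    Comparison is by exact sequence identity, ignoring modification state and
    missed-cleavage count.
    """
    if not per_species:
        raise ValueError("at least one species entry list is required")
    occurrence: dict[str, set[str]] = {}
    for species, entries in per_species.items():
        for e in entries:
            occurrence.setdefault(e.peptide.sequence, set()).add(species)
    annotated = []
    for species, entries in per_species.items():
        for e in entries:
            carriers = frozenset(occurrence[e.peptide.sequence] | {species})
            annotated.append(
                PeptideEntry(
                    accession=e.accession,
                    species=e.species,
                    peptide=e.peptide,
                    missed_cleavages=e.missed_cleavages,
                    mz=e.mz,
                    specificity=PROTEOTYPIC if len(carriers) == 1 else SHARED,
                    shared_species=carriers,
                )
            )
    return TheoreticalTable(
        entries=tuple(annotated),
        params=params,
        panel_species=frozenset(per_species),
    )


_COLUMNS = [
    "accession",
    "species",
    "sequence",
    "oxidized_positions",
    "missed_cleavages",
    "mz",
    "specificity",
    "shared_species",
]


def write_table(table: TheoreticalTable, path: str | Path) -> None:
    rows = [
        {
            "accession": e.accession,
            "species": e.species,
            "sequence": e.peptide.sequence,
            "oxidized_positions": ";".join(str(p) for p in sorted(e.peptide.oxidized_positions)),
            "missed_cleavages": e.missed_cleavages,
            "mz": f"{e.mz:.6f}",
            "specificity": e.specificity,
            "shared_species": ";".join(sorted(e.shared_species)),
        }
        for e in table.entries
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    header_meta = (
        f"# max_missed_cleavages={table.params.max_missed_cleavages}"
        f" mz_min={table.params.mz_min} mz_max={table.params.mz_max}"
        f" panel_species={';'.join(sorted(table.panel_species))}\n"
    )
    with open(path, "w") as fh:
        fh.write(header_meta)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> TheoreticalTable:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError(f"{path}:1: missing metadata header line")
        meta = dict(
            kv.split("=", 1) for kv in meta_line.lstrip("#").split() if "=" in kv
        )
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    entries = []
    for idx, row in df.iterrows():
        try:
            value = float(row["mz"])
            mc = int(row["missed_cleavages"])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row {idx + 3}: {exc}") from None
        ox = frozenset(int(p) for p in row["oxidized_positions"].split(";") if p)
        shared = frozenset(s for s in row["shared_species"].split(";") if s)
        entries.append(
            PeptideEntry(
                accession=row["accession"],
                species=row["species"],
                peptide=Peptide(row["sequence"], ox),
                missed_cleavages=mc,
                mz=value,
                specificity=row["specificity"],
                shared_species=shared,
            )
        )
    params = DigestParams(
        max_missed_cleavages=int(meta.get("max_missed_cleavages", 2)),
        mz_min=float(meta.get("mz_min", 600.0)),
        mz_max=float(meta.get("mz_max", 2000.0)),
    )
    species = frozenset(s for s in meta.get("panel_species", "").split(";") if s)
    return TheoreticalTable(entries=tuple(entries), params=params, panel_species=species)
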