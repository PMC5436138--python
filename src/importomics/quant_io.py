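"""Input/output of quantification tables, reference sets and sequences.

Quantification tables are tab-separated with one header row, in the dialect
of search-engine protein-group output (one row per protein group, one raw
heavy/light ratio column per biological replicate).  Ratios are re-oriented
at read time to a common +Tet/-Tet (knockdown-induced over uninduced)
direction using the replicate design, which records which replicates were
label-switched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

HEAVY = "heavy"
LIGHT = "light"

EVIDENCE_MSMS = "msms"
EVIDENCE_MBR = "match_between_runs"
EVIDENCE_ABSENT = "absent"
_EVIDENCE_VALUES = frozenset({EVIDENCE_MSMS, EVIDENCE_MBR, EVIDENCE_ABSENT})

#: residues accepted in protein sequences (20 standard amino acids plus X).
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class QuantTableFormatError(ValueError):
    """A quantification table does not match the declared column layout."""


@dataclass(frozen=True)
class Replicate:
    """One biological replicate and the isotope channel its induced sample got."""

    replicate_id: str
    induced_channel: str  # "heavy" or "light" (label-switched)

    def __post_init__(self) -> None:
        if self.induced_channel not in (HEAVY, LIGHT):
            raise ValueError(
                f"induced_channel must be {HEAVY!r} or {LIGHT!r}, "
                f"got {self.induced_channel!r}"
            )


@dataclass(frozen=True)
class ReplicateDesign:
    """Replicate layout of one knockdown experiment, label switches included."""

    replicates: tuple[Replicate, ...]
    labeling_scheme: str = "silac"  # "silac" or "dimethyl"

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a replicate design needs at least one replicate")
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValueError(f"replicate ids are not unique: {ids}")
        if self.labeling_scheme not in ("silac", "dimethyl"):
            raise ValueError(f"unknown labeling scheme {self.labeling_scheme!r}")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(r.replicate_id for r in self.replicates)

    def orientation_signs(self) -> np.ndarray:
        """+1 where log2(H/L) already points in the +Tet/-Tet direction, -1 where switched."""
        return np.array(
            [1.0 if r.induced_channel == HEAVY else -1.0 for r in self.replicates]
        )


@dataclass
class ProteinQuantRecord:
    """One protein's oriented per-replicate ratios and identification metadata.

    ``log2_ratios`` holds oriented log2(+Tet/-Tet) values with ``nan`` for
    replicates in which the protein was not quantified; its length equals the
    design size, as does ``evidence``.
    """

    protein_id: str
    description: str
    n_peptides: int
    n_unique_peptides: int
    log2_ratios: np.ndarray
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if self.n_peptides < 0 or self.n_unique_peptides < 0:
            raise ValueError("peptide counts must be non-negative")
        if self.n_unique_peptides > self.n_peptides:
            raise ValueError(
                f"{self.protein_id}: n_unique_peptides ({self.n_unique_peptides}) "
                f"> n_peptides ({self.n_peptides})"
            )
        if len(self.evidence) != len(self.log2_ratios):
            raise ValueError(
                f"{self.protein_id}: {len(self.evidence)} evidence slots for "
                f"{len(self.log2_ratios)} ratio slots"
            )
        for ev, ratio in zip(self.evidence, self.log2_ratios):
            if ev not in _EVIDENCE_VALUES:
                raise ValueError(f"{self.protein_id}: unknown evidence value {ev!r}")
            if ev == EVIDENCE_ABSENT and not math.isnan(ratio):
                raise ValueError(
                    f"{self.protein_id}: replicate marked absent carries a ratio"
                )

    @property
    def n_quantified(self) -> int:
        return int(np.sum(~np.isnan(self.log2_ratios)))


@dataclass(frozen=True)
class ReferenceSet:
    """A named set of protein accessions (e.g. the organellar reference proteome)."""

    name: str
    ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"reference set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, accession: str) -> bool:
        return accession in self.ids


@dataclass(frozen=True)
class ProteinSequenceRecord:
    """An amino-acid sequence keyed by accession; upper case, standard alphabet + X."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from record fields to column names of a quantification table.

    ``ratio_columns`` and ``evidence_columns`` map replicate ids to column
    names; ``evidence_columns`` may be empty, in which case quantified
    replicates are treated as MS/MS-identified.  The defaults are the dialect
    the synthetic generator emits; real tables are absorbed by overriding
    names in the run configuration.
    """

    protein_id: str = "protein_id"
    description: str = "description"
    n_peptides: str = "n_peptides"
    n_unique_peptides: str = "n_unique_peptides"
    ratio_columns: Mapping[str, str] = field(default_factory=dict)
    evidence_columns: Mapping[str, str] = field(default_factory=dict)

    @staticmethod
    def default_for(design: ReplicateDesign) -> "ColumnMap":
        return ColumnMap(
            ratio_columns={r: f"ratio_hl_{r}" for r in design.replicate_ids},
            evidence_columns={r: f"evidence_{r}" for r in design.replicate_ids},
        )


def read_quant_table(
    path: str | Path,
    design: ReplicateDesign,
    columns: ColumnMap | None = None,
) -> list[ProteinQuantRecord]:
    """Read a protein-group table and orient raw H/L ratios to +Tet/-Tet.

    For replicates whose induced sample carried the heavy label the oriented
    value is ``log2(H/L)``; for label-switched replicates it is ``-log2(H/L)``.
    Missing or non-numeric ratio cells become missing values; non-positive
    ratios raise, since a search-engine ratio can never be <= 0.
    """
    path = Path(path)
    if columns is None:
        columns = ColumnMap.default_for(design)

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    required = [columns.protein_id, columns.n_peptides, columns.n_unique_peptides]
    for rep_id in design.replicate_ids:
        if rep_id not in columns.ratio_columns:
            raise QuantTableFormatError(
                f"no ratio column mapped for replicate {rep_id!r}"
            )
        required.append(columns.ratio_columns[rep_id])
    required.extend(
        columns.evidence_columns[r]
        for r in design.replicate_ids
        if r in columns.evidence_columns
    )
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise QuantTableFormatError(
            f"{path.name}: missing column(s) {missing}; found {list(table.columns)}"
        )

    signs = design.orientation_signs()
    has_description = columns.description in table.columns

    records: list[ProteinQuantRecord] = []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        row_map = dict(zip(table.columns, row))
        ratios = np.full(design.n_replicates, np.nan)
        evidence: list[str] = []
        for k, rep_id in enumerate(design.replicate_ids):
            cell = row_map[columns.ratio_columns[rep_id]].strip()
            raw = _parse_ratio(cell, path.name, row_number)
            if raw is not None:
                ratios[k] = signs[k] * math.log2(raw)
            ev_col = columns.evidence_columns.get(rep_id)
            if raw is None:
                evidence.append(EVIDENCE_ABSENT)
            elif ev_col is None:
                evidence.append(EVIDENCE_MSMS)
            else:
                ev = row_map[ev_col].strip() or EVIDENCE_MSMS
                if ev not in _EVIDENCE_VALUES:
                    raise QuantTableFormatError(
                        f"{path.name} row {row_number}: unknown evidence value {ev!r}"
                    )
                evidence.append(ev)
        records.append(
            ProteinQuantRecord(
                protein_id=row_map[columns.protein_id].strip(),
                description=row_map[columns.description].strip()
                if has_description
                else "",
                n_peptides=int(row_map[columns.n_peptides]),
                n_unique_peptides=int(row_map[columns.n_unique_peptides]),
                log2_ratios=ratios,
                evidence=tuple(evidence),
            )
        )
    return records


def _parse_ratio(cell: str, filename: str, row_number: int) -> float | None:
    if cell in ("", "NaN", "nan", "NA"):
        return None
    try:
        value = float(cell)
    except ValueError:
        return None
    if math.isnan(value):
        return None
    if value <= 0:
        raise ValueError(
            f"{filename} row {row_number}: non-positive raw ratio {value}"
        )
    return value


def read_reference_set(path: str | Path, name: str) -> ReferenceSet:
    """Read a one-accession-per-line reference list ("#" starts a comment)."""
    path = Path(path)
    ids: list[str] = []
    for line in path.read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.append(entry)
    if not ids:
        raise ValueError(f"reference set file {path} contains no accessions")
    unique = frozenset(ids)
    if len(unique) < len(ids):
        log.warning(
            "reference set %s: %d duplicate accession(s) collapsed",
            name,
            len(ids) - len(unique),
        )
    log.info("reference set %s: %d accessions", name, len(unique))
    return ReferenceSet(name=name, ids=unique)


def read_fasta(path: str | Path) -> list[ProteinSequenceRecord]:
    """Read protein sequences; the accession is the header's first token."""
    records: list[ProteinSequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(entry.seq).upper().rstrip("*")
        if not sequence:
            raise ValueError(f"empty sequence for {accession!r} in {path}")
        records.append(ProteinSequenceRecord(protein_id=accession, sequence=sequence))
    return records


def write_results_table(records, path: str | Path) -> None:
    """Write a homogeneous result collection as TSV (missing values empty).

    Accepts a DataFrame or a sequence of dataclass instances sharing one
    type; column order is the dataclass field order and therefore stable.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if records and is_dataclass(records[0]):
            cols = [f.name for f in fields(records[0])]
            frame = pd.DataFrame([asdict(r) for r in records], columns=cols)
        else:
            frame = pd.DataFrame(records)
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")


def quant_records_to_table(
    records: Iterable[ProteinQuantRecord],
    design: ReplicateDesign,
    columns: ColumnMap | None = None,
) -> pd.DataFrame:
    """Serialize oriented records back to the raw H/L table dialect.

    Inverse of :func:`read_quant_table`: oriented ratios are converted back
    to raw heavy/light values respecting the design's label switches, so a
    write/read round trip reproduces the oriented values.
    """
    if columns is None:
        columns = ColumnMap.default_for(design)
    signs = design.orientation_signs()
    rows = []
    for rec in records:
        row: dict[str, object] = {
            columns.protein_id: rec.protein_id,
            columns.description: rec.description,
            columns.n_peptides: rec.n_peptides,
            columns.n_unique_peptides: rec.n_unique_peptides,
        }
        for k, rep_id in enumerate(design.replicate_ids):
            oriented = rec.log2_ratios[k]
            ratio_col = columns.ratio_columns[rep_id]
            row[ratio_col] = (
                "" if math.isnan(oriented) else repr(float(2.0 ** (signs[k] * oriented)))
            )
            ev_col = columns.evidence_columns.get(rep_id)
            if ev_col is not None:
                row[ev_col] = rec.evidence[k]
        rows.append(row)
    ordered = [columns.protein_id, columns.description, columns.n_peptides,
               columns.n_unique_peptides]
    for rep_id in design.replicate_ids:
        ordered.append(columns.ratio_columns[rep_id])
        if rep_id in columns.evidence_columns:
            ordered.append(columns.evidence_columns[rep_id])
    return pd.DataFrame(rows, columns=ordered)
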