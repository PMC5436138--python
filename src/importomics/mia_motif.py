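"""Twin-Cx3C/Cx9C motif scanning for disulfide-relay (MIA) substrate prediction.

Soluble cysteine-rich intermembrane-space proteins imported through the
disulfide relay classically carry two motifs of the form C-x(n)-C with
n = 3 or n = 9, where x is any residue except cysteine.  Candidate
substrates are small proteins (average mass below 50 kDa) carrying at least
two such motifs.  The scanner is greedy and non-overlapping: it walks the
sequence left to right and a cysteine consumed by one motif cannot open the
next, so runs of closely spaced cysteines are not inflated into twins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from importomics.quant_io import ProteinSequenceRecord

#: average (isotope-averaged) residue masses in Daltons, Expasy values
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}
#: X (unknown residue) contributes the mean of the 20 standard masses
AVERAGE_RESIDUE_MASS["X"] = sum(
    AVERAGE_RESIDUE_MASS[a] for a in "ACDEFGHIKLMNPQRSTVWY"
) / 20.0

WATER_MASS_DA = 18.0153

#: fraction of X residues above which a prediction is flagged as unreliable
HIGH_X_FRACTION = 0.10


@dataclass(frozen=True)
class MotifHit:
    """One C-x(n)-C occurrence; positions are 1-based inclusive."""

    protein_id: str
    motif_type: str  # "Cx3C" or "Cx9C"
    start: int  # position of the opening cysteine
    end: int  # position of the closing cysteine


@dataclass
class MiaPrediction:
    protein_id: str
    average_mass_da: float
    hits: list[MotifHit] = field(default_factory=list)
    n_cx3c: int = 0
    n_cx9c: int = 0
    is_predicted_substrate: bool = False
    high_x_content: bool = False


def average_mass(sequence: str) -> float:
    """Average molecular mass of a peptide chain in Daltons.

    Sum of average residue masses plus one water for the termini.  X counts
    as the mean standard residue; any other non-standard letter raises.
    """
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    mass = WATER_MASS_DA
    for letter in sequence:
        try:
            mass += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise ValueError(f"unknown residue {letter!r} in sequence") from None
    return mass


def find_twin_cx_motifs(
    sequence: str, spacing: int, protein_id: str = ""
) -> list[MotifHit]:
    """Greedy left-to-right scan for non-overlapping C-x(spacing)-C motifs.

    The x positions must not be cysteine; after a hit the scan resumes
    after the closing cysteine, so hits never share residues.
    """
    if spacing < 1:
        raise ValueError("spacing must be at least 1")
    motif_type = f"Cx{spacing}C"
    pattern = re.compile(f"C[^C]{{{spacing}}}C")
    hits: list[MotifHit] = []
    # re.finditer is non-overlapping and resumes after each match end,
    # which is exactly the greedy policy.
    for match in pattern.finditer(sequence):
        hits.append(
            MotifHit(
                protein_id=protein_id,
                motif_type=motif_type,
                start=match.start() + 1,
                end=match.end(),
            )
        )
    return hits


CountMode = Literal["same-type", "total"]


def predict_mia_substrates(
    sequences: Iterable[ProteinSequenceRecord],
    mass_cutoff_da: float = 50_000.0,
    min_motifs: int = 2,
    spacings: Sequence[int] = (3, 9),
    count_mode: CountMode = "same-type",
) -> list[MiaPrediction]:
    """Predict classical disulfide-relay substrates for every input protein.

    A protein is predicted when its average mass is strictly below
    ``mass_cutoff_da`` and it carries at least ``min_motifs`` motifs — of
    one type under the default ``same-type`` counting (the classical twin
    arrangement), or summed across types under ``total``.
    Predictions are returned for all inputs, not only positives.
    """
    if min_motifs < 1:
        raise ValueError("min_motifs must be at least 1")
    predictions: list[MiaPrediction] = []
    for record in sequences:
        hits: list[MotifHit] = []
        per_type: dict[int, int] = {}
        for spacing in spacings:
            found = find_twin_cx_motifs(record.sequence, spacing, record.protein_id)
            per_type[spacing] = len(found)
            hits.extend(found)
        hits.sort(key=lambda h: h.start)
        if count_mode == "same-type":
            effective = max(per_type.values()) if per_type else 0
        elif count_mode == "total":
            effective = sum(per_type.values())
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
        mass = average_mass(record.sequence)
        x_fraction = record.sequence.count("X") / len(record.sequence)
        predictions.append(
            MiaPrediction(
                protein_id=record.protein_id,
                average_mass_da=mass,
                hits=hits,
                n_cx3c=per_type.get(3, 0),
                n_cx9c=per_type.get(9, 0),
                is_predicted_substrate=(
                    mass < mass_cutoff_da and effective >= min_motifs
                ),
                high_x_content=x_fraction > HIGH_X_FRACTION,
            )
        )
    return predictions


def predictions_to_rows(predictions: Sequence[MiaPrediction]) -> list[dict]:
    """Serialize predictions for TSV export (motif coordinates as a string)."""
    rows = []
    for p in predictions:
        coords = ";".join(f"{h.motif_type}:{h.start}-{h.end}" for h in p.hits)
        rows.append(
            {
                "protein_id": p.protein_id,
                "average_mass_da": round(p.average_mass_da, 2),
                "n_cx3c": p.n_cx3c,
                "n_cx9c": p.n_cx9c,
                "motif_coordinates": coords,
                "is_predicted_substrate": p.is_predicted_substrate,
                "high_x_content": p.high_x_content,
            }
        )
    return rows
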