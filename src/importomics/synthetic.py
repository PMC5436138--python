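"""Synthetic knockdown-proteomics datasets and proteomes with known truth.

The quantification generator emulates the statistical structure of an
import-factor knockdown experiment: an organellar protein population whose
abundance in the organelle fraction drops on knockdown (protein-level log2
effect drawn around ``effect_mean``) and a non-organellar population centred
at zero, both observed through per-replicate log2 ratio noise, with
label-switched replicates, heavy-tailed peptide counts, per-replicate
identification evidence and missing ratios.  Reference sets cover a
configurable fraction of each class, leaving an unlabeled pool that mimics
unannotated proteins.

The proteome generator plants twin C-x(n)-C motifs into cysteine-free
random backbones so the motif scanner's output can be checked against the
planted coordinates exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from importomics.mia_motif import MotifHit, average_mass
from importomics.quant_io import (
    EVIDENCE_ABSENT,
    EVIDENCE_MBR,
    EVIDENCE_MSMS,
    HEAVY,
    LIGHT,
    ColumnMap,
    ProteinQuantRecord,
    ProteinSequenceRecord,
    ReferenceSet,
    Replicate,
    ReplicateDesign,
    quant_records_to_table,
)

ORGANELLAR = "organellar"
OTHER = "other"

#: residues used for random backbones: the 19 standard letters minus C,
#: so every cysteine in a generated sequence is a planted one.
_BACKBONE_ALPHABET = np.array(list("ADEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticQuantConfig:
    """Study conditions of the simulated knockdown experiment.

    Defaults are the package's reference scenario: 800 organellar + 800
    other proteins, four replicates including one label switch, a -1.5 log2
    mean depletion with 0.5 between-protein spread, 0.4 within-protein
    replicate noise, 5% missing ratios and 60% reference coverage.
    """

    n_organellar: int = 800
    n_other: int = 800
    n_replicates: int = 4
    effect_mean: float = -1.5  # expected log2 depletion of organellar proteins
    effect_sd: float = 0.5  # between-protein spread of the true effect
    replicate_sd: float = 0.4  # within-protein per-replicate noise
    label_switch_replicates: tuple[int, ...] = (3,)  # 0-based indices
    missing_rate: float = 0.05
    peptide_nbinom_r: float = 1.2  # n_peptides = 1 + NegBin(r, p), heavy-tailed
    peptide_nbinom_p: float = 0.25
    evidence_msms_prob: float = 0.85  # MS/MS vs match-between-runs, given quantified
    reference_coverage: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_organellar, self.n_other) < 0 or self.n_replicates < 1:
            raise ValueError("protein and replicate counts must be non-negative")
        for name in ("missing_rate", "evidence_msms_prob", "reference_coverage"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        if self.effect_mean >= 0:
            raise ValueError("effect_mean must be negative for a depletion scenario")
        if min(self.effect_sd, self.replicate_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(not 0 <= i < self.n_replicates for i in self.label_switch_replicates):
            raise ValueError("label_switch_replicates indices out of range")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, keyed by accession."""

    class_of: dict[str, str] = field(default_factory=dict)
    effect_of: dict[str, float] = field(default_factory=dict)
    motif_coordinates: dict[str, list[MotifHit]] = field(default_factory=dict)
    is_substrate: dict[str, bool] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    records: list[ProteinQuantRecord]
    design: ReplicateDesign
    positive_reference: ReferenceSet | None
    negative_reference: ReferenceSet | None
    truth: SyntheticTruth


def _make_design(config: SyntheticQuantConfig) -> ReplicateDesign:
    switched = set(config.label_switch_replicates)
    return ReplicateDesign(
        replicates=tuple(
            Replicate(
                replicate_id=f"rep{i + 1}",
                induced_channel=LIGHT if i in switched else HEAVY,
            )
            for i in range(config.n_replicates)
        )
    )


def simulate_quant_dataset(config: SyntheticQuantConfig) -> SyntheticDataset:
    """Generate oriented quantification records plus reference sets and truth.

    Per organellar protein the true effect is Normal(effect_mean,
    effect_sd^2); other proteins have effect 0.  Each replicate observes
    effect + Normal(0, replicate_sd^2); ratios are dropped at
    ``missing_rate``.  A fixed seed gives identical output across runs.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n_total = config.n_organellar + config.n_other
    ids = [f"ORG{i + 1:05d}" for i in range(config.n_organellar)] + [
        f"OTH{i + 1:05d}" for i in range(config.n_other)
    ]
    classes = [ORGANELLAR] * config.n_organellar + [OTHER] * config.n_other

    effects = np.zeros(n_total)
    if config.n_organellar:
        effects[: config.n_organellar] = rng.normal(
            config.effect_mean, config.effect_sd, size=config.n_organellar
        )

    noise = rng.normal(0.0, config.replicate_sd, size=(n_total, config.n_replicates))
    ratios = effects[:, None] + noise
    missing = rng.random((n_total, config.n_replicates)) < config.missing_rate
    ratios[missing] = np.nan

    n_peptides = 1 + rng.negative_binomial(
        config.peptide_nbinom_r, config.peptide_nbinom_p, size=n_total
    )
    n_unique = 1 + rng.binomial(n_peptides - 1, 0.8)

    msms = rng.random((n_total, config.n_replicates)) < config.evidence_msms_prob

    records: list[ProteinQuantRecord] = []
    truth = SyntheticTruth()
    for i, (protein_id, cls) in enumerate(zip(ids, classes)):
        evidence = tuple(
            EVIDENCE_ABSENT if missing[i, k] else (EVIDENCE_MSMS if msms[i, k] else EVIDENCE_MBR)
            for k in range(config.n_replicates)
        )
        records.append(
            ProteinQuantRecord(
                protein_id=protein_id,
                description=f"synthetic {cls} protein",
                n_peptides=int(n_peptides[i]),
                n_unique_peptides=int(n_unique[i]),
                log2_ratios=ratios[i].copy(),
                evidence=evidence,
            )
        )
        truth.class_of[protein_id] = cls
        truth.effect_of[protein_id] = float(effects[i]) if cls == ORGANELLAR else 0.0

    positive = _sample_reference(
        rng, ids[: config.n_organellar], config.reference_coverage, "organellar_reference"
    )
    negative = _sample_reference(
        rng, ids[config.n_organellar :], config.reference_coverage, "non_organellar_reference"
    )
    return SyntheticDataset(
        records=records,
        design=design,
        positive_reference=positive,
        negative_reference=negative,
        truth=truth,
    )


def _sample_reference(
    rng: np.random.Generator, ids: Sequence[str], coverage: float, name: str
) -> ReferenceSet | None:
    size = round(coverage * len(ids))
    if size == 0:
        return None
    chosen = rng.choice(np.array(ids), size=size, replace=False)
    return ReferenceSet(name=name, ids=frozenset(str(x) for x in chosen))


def simulate_proteome_sequences(
    n_proteins: int,
    substrate_fraction: float = 0.3,
    mean_length: int = 150,
    length_sigma: float = 0.45,
    seed: int = 0,
) -> tuple[list[ProteinSequenceRecord], SyntheticTruth]:
    """Generate a proteome with planted twin C-x(n)-C motifs and known truth.

    Substrate proteins carry two or three disjoint same-type motifs in a
    cysteine-free backbone and stay below the 50 kDa mass gate; non-substrate
    proteins carry at most one motif (or a mis-spaced C-x(5)-C pair) so the
    scanner can never find a twin.  Lengths follow a lognormal law around
    ``mean_length``.
    """
    if not 0.0 <= substrate_fraction <= 1.0:
        raise ValueError("substrate_fraction must be a probability")
    rng = np.random.default_rng(seed)
    records: list[ProteinSequenceRecord] = []
    truth = SyntheticTruth()
    n_substrates = round(substrate_fraction * n_proteins)
    for i in range(n_proteins):
        protein_id = f"SYN{i + 1:05d}"
        is_substrate = i < n_substrates
        length = int(
            np.clip(rng.lognormal(math.log(mean_length), length_sigma), 40, 700)
        )
        if is_substrate:
            length = min(length, 350)  # keeps the average mass below 50 kDa
            spacing = int(rng.choice([3, 9]))
            n_motifs = int(rng.integers(2, 4))
            sequence, hits = _plant_motifs(rng, length, spacing, n_motifs, protein_id)
            if average_mass(sequence) >= 50_000.0:  # pragma: no cover - safety net
                sequence, hits = _plant_motifs(rng, 150, spacing, n_motifs, protein_id)
        else:
            kind = rng.choice(["none", "single3", "single9", "misspaced"])
            if kind == "none":
                sequence = _backbone(rng, length)
                hits = []
            elif kind == "misspaced":
                sequence, hits = _plant_motifs(rng, length, 5, 2, protein_id)
                hits = []  # Cx5C pairs are not Cx3C/Cx9C motifs
            else:
                spacing = 3 if kind == "single3" else 9
                sequence, hits = _plant_motifs(rng, length, spacing, 1, protein_id)
        records.append(ProteinSequenceRecord(protein_id=protein_id, sequence=sequence))
        truth.motif_coordinates[protein_id] = hits
        truth.is_substrate[protein_id] = is_substrate
    return records, truth


def _backbone(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BACKBONE_ALPHABET, size=length))


def _plant_motifs(
    rng: np.random.Generator,
    length: int,
    spacing: int,
    n_motifs: int,
    protein_id: str,
) -> tuple[str, list[MotifHit]]:
    """Build a sequence of ~``length`` residues with disjoint planted motifs.

    Motifs are separated by at least one cysteine-free residue, so the
    greedy scanner recovers exactly the planted coordinates.
    """
    motif_len = spacing + 2
    min_needed = n_motifs * motif_len + (n_motifs + 1)
    length = max(length, min_needed)
    spare = length - n_motifs * motif_len - (n_motifs + 1)
    # distribute the spare residues over the n_motifs + 1 gaps
    cuts = np.sort(rng.integers(0, spare + 1, size=n_motifs))
    gap_sizes = np.diff(np.concatenate([[0], cuts, [spare]])) + 1
    # an inter-motif gap of exactly 3 or 9 would let the closing C of one
    # motif and the opening C of the next form an accidental cross-motif of
    # the other spacing; bump such gaps by one residue
    for k in range(1, n_motifs):
        if gap_sizes[k] in (3, 9):
            gap_sizes[k] += 1

    parts: list[str] = []
    hits: list[MotifHit] = []
    position = 0
    for k in range(n_motifs):
        gap = _backbone(rng, int(gap_sizes[k]))
        parts.append(gap)
        position += len(gap)
        motif = "C" + _backbone(rng, spacing) + "C"
        parts.append(motif)
        hits.append(
            MotifHit(
                protein_id=protein_id,
                motif_type=f"Cx{spacing}C",
                start=position + 1,
                end=position + motif_len,
            )
        )
        position += motif_len
    parts.append(_backbone(rng, int(gap_sizes[-1])))
    return "".join(parts), hits


def analytic_import_call_probability(
    threshold: float,
    n_quantified: int,
    replicate_sd: float,
    effect_mean: float = 0.0,
    effect_sd: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Probability that a protein of the normal model is called imported.

    Under the generator's model a protein with true effect e ~ Normal(
    effect_mean, effect_sd^2) observed in ``n_quantified`` replicates has a
    sample mean m ~ Normal(effect_mean, effect_sd^2 + replicate_sd^2/n) and
    an independent sample sd s with (n-1)s^2/replicate_sd^2 ~ chi-square.
    The protein is called when m <= threshold and the one-sample t-test
    rejects, i.e. s < |m| sqrt(n) / t_crit.  The double integral collapses
    to a one-dimensional integral over m, evaluated numerically.

    With ``effect_mean=0, effect_sd=0`` this is the false-call probability
    of an unaffected protein; one minus that is the expected specificity.
    """
    from scipy import integrate, stats as sps

    n = n_quantified
    if n < 2:
        return 0.0
    df = n - 1
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    m_sd = math.sqrt(effect_sd**2 + replicate_sd**2 / n)

    def integrand(m: float) -> float:
        s_limit = abs(m) * math.sqrt(n) / t_crit
        p_reject = sps.chi2.cdf(df * s_limit**2 / replicate_sd**2, df)
        return sps.norm.pdf(m, loc=effect_mean, scale=m_sd) * p_reject

    lower = min(effect_mean - 10 * m_sd, threshold - 1.0)
    value, _ = integrate.quad(integrand, lower, threshold, limit=200)
    return float(min(max(value, 0.0), 1.0))


# ---------------------------------------------------------------------------
# fixture emission

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact dialect the readers consume.

    Emits the raw H/L quantification table (label switches applied in
    reverse), both reference lists and a truth table; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = quant_records_to_table(dataset.records, dataset.design)
    paths["quant_table"] = outdir / "quant_table.tsv"
    table.to_csv(paths["quant_table"], sep="\t", index=False)

    for key, ref in (
        ("positive_reference", dataset.positive_reference),
        ("negative_reference", dataset.negative_reference),
    ):
        if ref is None:
            continue
        paths[key] = outdir / f"{key}.txt"
        paths[key].write_text(
            f"# {ref.name}\n" + "\n".join(sorted(ref.ids)) + "\n"
        )

    paths["truth"] = outdir / "truth.tsv"
    with paths["truth"].open("w") as fh:
        fh.write("protein_id\tclass\ttrue_effect\n")
        for protein_id, cls in dataset.truth.class_of.items():
            fh.write(f"{protein_id}\t{cls}\t{dataset.truth.effect_of[protein_id]!r}\n")
    return paths


def write_fasta(records: Sequence[ProteinSequenceRecord], path: str | Path) -> None:
    """Write sequences as wrapped FASTA."""
    with Path(path).open("w") as fh:
        for record in records:
            fh.write(f">{record.protein_id}\n")
            for start in range(0, len(record.sequence), 60):
                fh.write(record.sequence[start : start + 60] + "\n")
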