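import math

import numpy as np
import pytest

from importomics import (
    ColumnMap,
    ProteinStatistics,
    ReferenceSet,
    Replicate,
    ReplicateDesign,
)


@pytest.fixture
def design4():
    """Four replicates, last one label-switched."""
    return ReplicateDesign(
        replicates=(
            Replicate("rep1", "heavy"),
            Replicate("rep2", "heavy"),
            Replicate("rep3", "heavy"),
            Replicate("rep4", "light"),
        )
    )


@pytest.fixture
def design2():
    return ReplicateDesign(
        replicates=(Replicate("rep1", "heavy"), Replicate("rep2", "light"))
    )


def make_stat(protein_id, mean, p=0.01, passed=True, n=3):
    """A ProteinStatistics carrying only what classification needs."""
    return ProteinStatistics(
        protein_id=protein_id,
        ratios=np.full(n, mean),
        n_quantified=0 if math.isnan(mean) else n,
        mean_log2=mean,
        p_value=p,
        passed_filter=passed,
    )


def make_stats(means_by_id, p=0.01):
    return [make_stat(pid, mean, p=p) for pid, mean in means_by_id.items()]


def refset(name, *ids):
    return ReferenceSet(name=name, ids=frozenset(ids))


def write_quant_tsv(path, design, rows, columns=None):
    """Write a raw H/L quant table from (id, npep, nuniq, raw_ratios, evidence)."""
    columns = columns or ColumnMap.default_for(design)
    header = [columns.protein_id, columns.n_peptides, columns.n_unique_peptides]
    for rep in design.replicate_ids:
        header.append(columns.ratio_columns[rep])
        if rep in columns.evidence_columns:
            header.append(columns.evidence_columns[rep])
    lines = ["\t".join(header)]
    for pid, npep, nuniq, ratios, evidence in rows:
        cells = [pid, str(npep), str(nuniq)]
        for k, rep in enumerate(design.replicate_ids):
            cells.append("" if ratios[k] is None else repr(ratios[k]))
            if rep in columns.evidence_columns:
                cells.append(evidence[k])
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
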