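from pathlib import Path

import numpy as np
import pytest

from t1dprs import (
    GenotypeMatrix,
    SNPPanel,
    SNPRecord,
    SubjectTable,
    load_panel,
)


@pytest.fixture(scope="session")
def panel() -> SNPPanel:
    return load_panel()


@pytest.fixture(scope="session")
def mini_panel() -> SNPPanel:
    """Four-SNP panel spanning SNV risk-on-ALT, risk-on-REF, and both indel codes."""
    return SNPPanel(
        [
            SNPRecord("rs2476601", "A", 0.64, "1", 114377568),
            SNPRecord("rs61839660", "T", -0.48, "10", 6094697),
            SNPRecord("rs540653847", "I", 1.78, "6", 31274794),
            SNPRecord("rs371250843", "D", 0.39, "6", 31324737),
        ]
    )


def make_genotypes(panel, dosages, missing=None, ids=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    if missing is None:
        missing = np.zeros_like(dosages, dtype=bool)
    if ids is None:
        ids = [f"S{i}" for i in range(len(dosages))]
    return GenotypeMatrix(ids, dosages, np.asarray(missing, bool), panel)


def make_subjects(n_cases, n_controls, n_aux=0) -> SubjectTable:
    ids = [f"S{i}" for i in range(n_cases + n_controls + n_aux)]
    labels = ["case"] * n_cases + ["control"] * n_controls + ["aux_control"] * n_aux
    return SubjectTable(ids, labels)


def write_vcf(path: Path, samples, rows) -> Path:
    """Write a minimal VCF.  rows: (chrom, pos, vid, ref, alts, gts) with gts a
    list of 'a/b' strings per sample."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, vid, ref, alts, gts in rows:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
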