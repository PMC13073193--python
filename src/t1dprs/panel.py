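"""SNP panel loading, genotype ingestion and feature encoding.

The package ships a 67-variant type 1 diabetes panel (GRCh37) in which each
variant carries a risk allele and a signed log-odds weight (beta).  Subject
genotypes are represented as *risk-allele dosages*: the number of copies of
the risk allele carried (0, 1 or 2), regardless of whether the risk allele is
REF or ALT in the source file.  Two feature encodings are supported: the raw
dosage (``count``) and the dosage multiplied by the per-SNP beta
(``beta_weighted``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGTID")
_DEFAULT_PANEL_RESOURCE = "snp_panel_grch37.tsv"


class PanelValidationError(ValueError):
    """Raised when a SNP panel violates its invariants."""


class AlleleMismatchError(ValueError):
    """Raised when a source variant cannot be oriented to the panel risk allele."""


@dataclass(frozen=True)
class SNPRecord:
    """One panel variant: identity, risk allele and effect weight."""

    rsid: str
    risk_allele: str
    beta: float
    chromosome: str
    position: int
    genes: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise PanelValidationError("rsid must be non-empty")
        if self.risk_allele not in VALID_ALLELES:
            raise PanelValidationError(
                f"{self.rsid}: risk allele {self.risk_allele!r} not in {sorted(VALID_ALLELES)}"
            )
        if not np.isfinite(self.beta):
            raise PanelValidationError(f"{self.rsid}: beta must be finite")
        if self.position <= 0:
            raise PanelValidationError(f"{self.rsid}: position must be positive")


@dataclass
class SNPPanel:
    """Ordered list of panel variants; the order fixes feature order downstream."""

    records: list[SNPRecord]
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise PanelValidationError(f"duplicate rsids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.records], dtype=float)

    @property
    def chromosomes(self) -> list[str]:
        return [r.chromosome for r in self.records]

    def index_of(self, rsid: str) -> int:
        return self.rsids.index(rsid)

    def record(self, rsid: str) -> SNPRecord:
        return self.records[self.index_of(rsid)]


@dataclass
class GenotypeMatrix:
    """Subjects x panel risk-allele dosages with a missingness mask.

    ``dosages`` is float so that expected-dosage imputation (values such as
    2q) can be carried through; observed entries are integers in {0, 1, 2}.
    """

    subject_ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    panel: SNPPanel

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match dosage rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if m != len(self.panel):
            raise ValueError(
                f"dosage columns ({m}) do not match panel size ({len(self.panel)})"
            )
        if self.missing_mask.shape != self.dosages.shape:
            raise ValueError("missing_mask shape mismatch")
        observed = self.dosages[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            raise ValueError("observed dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    @property
    def n_missing_columns(self) -> int:
        """Number of panel SNPs missing for every subject (e.g. absent from the source)."""
        return int(self.missing_mask.all(axis=0).sum())

    def subset(self, subject_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [idx[s] for s in subject_ids]
        return GenotypeMatrix(
            list(subject_ids),
            self.dosages[rows].copy(),
            self.missing_mask[rows].copy(),
            self.panel,
        )

    def to_dosage_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, index=self.subject_ids, columns=self.panel.rsids)
        return df.mask(self.missing_mask)


@dataclass
class SubjectTable:
    """Subject labels (case / control / aux_control) and optional subgroup tags."""

    subject_ids: list[str]
    labels: list[str]
    subgroups: list[str | None] = field(default_factory=list)

    VALID_LABELS = frozenset({"case", "control", "aux_control"})

    def __post_init__(self) -> None:
        if not self.subgroups:
            self.subgroups = [None] * len(self.subject_ids)
        if not (len(self.subject_ids) == len(self.labels) == len(self.subgroups)):
            raise ValueError("subject_ids, labels and subgroups must align")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        bad = sorted(set(self.labels) - self.VALID_LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}; allowed: {sorted(self.VALID_LABELS)}")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 for case, 0 otherwise."""
        return np.array([1 if l == "case" else 0 for l in self.labels], dtype=int)

    def label_of(self, subject_id: str) -> str:
        return self.labels[self.subject_ids.index(subject_id)]

    def subset(self, subject_ids: Sequence[str]) -> "SubjectTable":
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [idx[s] for s in subject_ids]
        return SubjectTable(
            list(subject_ids),
            [self.labels[i] for i in rows],
            [self.subgroups[i] for i in rows],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubjectTable":
        df = pd.read_csv(path, dtype=str)
        required = {"subject_id", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"subject table needs columns {sorted(required)}")
        subgroups: list[str | None]
        if "subgroup" in df.columns:
            subgroups = [None if pd.isna(v) else str(v) for v in df["subgroup"]]
        else:
            subgroups = [None] * len(df)
        return cls(list(df["subject_id"]), list(df["label"]), subgroups)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "label": self.labels,
                "subgroup": ["" if s is None else s for s in self.subgroups],
            }
        ).to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """Real-valued subjects x features matrix fed to a risk model."""

    values: np.ndarray
    feature_names: list[str]
    encoding: str
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape does not match subjects x feature_names")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


# ---------------------------------------------------------------------------
# Panel loading


def load_panel(path: str | Path | None = None) -> SNPPanel:
    """Load a SNP panel from TSV; with no argument, the packaged 67-SNP panel.

    The TSV must carry columns rsid, risk_allele, beta, chromosome, position
    (genes optional).
    """
    if path is None:
        ref = resources.files("t1dprs.data") / _DEFAULT_PANEL_RESOURCE
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"rsid", "risk_allele", "beta", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise PanelValidationError(f"panel file missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            beta = float(row.beta)
        except ValueError as exc:
            raise PanelValidationError(f"{row.rsid}: non-numeric beta {row.beta!r}") from exc
        records.append(
            SNPRecord(
                rsid=row.rsid,
                risk_allele=row.risk_allele,
                beta=beta,
                chromosome=str(row.chromosome),
                position=int(row.position),
                genes=getattr(row, "genes", "") or "",
            )
        )
    return SNPPanel(records)


# ---------------------------------------------------------------------------
# Genotype ingestion


def read_genotypes(source: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    """Read subject genotypes and orient them to panel risk-allele dosages.

    VCF sources (``.vcf``/``.vcf.gz``) are matched by ID, falling back to
    (chromosome, position); delimited matrices (anything else) are matched by
    rsid column header.  Panel variants absent from the source come back as
    all-missing columns, to be filled by Hardy-Weinberg imputation.
    """
    source = Path(source)
    if source.suffix == ".vcf" or source.name.endswith(".vcf.gz"):
        return _read_vcf(source, panel)
    return _read_dosage_matrix(source, panel)


def _read_dosage_matrix(path: Path, panel: SNPPanel) -> GenotypeMatrix:
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    subject_col = df.columns[0]
    subject_ids = [str(s) for s in df[subject_col]]
    n = len(subject_ids)
    m = len(panel)
    dosages = np.zeros((n, m), dtype=float)
    mask = np.ones((n, m), dtype=bool)
    for j, rsid in enumerate(panel.rsids):
        if rsid not in df.columns:
            continue
        col = df[rsid]
        for i, v in enumerate(col):
            if pd.isna(v) or v in {"", "NA", "nan"}:
                continue
            d = float(v)
            if d not in (0.0, 1.0, 2.0):
                raise ValueError(f"{rsid}: dosage cell {v!r} not in {{0,1,2,NA}}")
            dosages[i, j] = d
            mask[i, j] = False
    gm = GenotypeMatrix(subject_ids, dosages, mask, panel)
    if gm.n_missing_columns:
        logger.warning("%d panel SNPs absent from %s", gm.n_missing_columns, path)
    return gm


def _match_alt_index(record: SNPRecord, ref: str, alts: Sequence[str]) -> int | None:
    """Return the ALT index carrying the risk allele, or None if REF carries it.

    Raises AlleleMismatchError when neither REF nor any ALT can represent the
    risk allele.  Indel codes: I matches the longer of REF/ALT, D the shorter.
    """
    risk = record.risk_allele
    if risk in "ACGT":
        if ref == risk:
            return None
        for k, alt in enumerate(alts):
            if alt == risk:
                return k
        raise AlleleMismatchError(
            f"{record.rsid}: risk allele {risk} matches neither REF={ref} nor ALT={list(alts)}"
        )
    # I/D: compare allele lengths
    for k, alt in enumerate(alts):
        if len(alt) == len(ref):
            continue
        longer_is_alt = len(alt) > len(ref)
        if (risk == "I") == longer_is_alt:
            return k
        return None  # REF is the risk allele for this indel
    raise AlleleMismatchError(
        f"{record.rsid}: cannot orient indel risk allele {risk} with REF={ref}, ALT={list(alts)}"
    )


def _read_vcf(path: Path, panel: SNPPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    n = len(subject_ids)
    m = len(panel)
    dosages = np.zeros((n, m), dtype=float)
    mask = np.ones((n, m), dtype=bool)
    by_rsid = {r.rsid: j for j, r in enumerate(panel.records)}
    by_pos = {(r.chromosome.removeprefix("chr"), r.position): j for j, r in enumerate(panel.records)}

    for variant in vcf:
        j = by_rsid.get(variant.ID) if variant.ID else None
        if j is None:
            j = by_pos.get((str(variant.CHROM).removeprefix("chr"), variant.POS))
        if j is None:
            continue
        record = panel.records[j]
        alts = list(variant.ALT)
        alt_idx = _match_alt_index(record, variant.REF, alts)
        genotypes = variant.genotypes  # [[a1, a2, phased], ...]
        for i in range(n):
            alleles = genotypes[i][:-1]
            if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                logger.warning(
                    "%s: malformed or missing GT for subject %s; set missing",
                    record.rsid,
                    subject_ids[i],
                )
                continue
            if alt_idx is None:  # REF carries the risk allele
                d = sum(1 for a in alleles if a == 0)
            else:
                d = sum(1 for a in alleles if a == alt_idx + 1)
            dosages[i, j] = d
            mask[i, j] = False
    gm = GenotypeMatrix(subject_ids, dosages, mask, panel)
    if gm.n_missing_columns:
        logger.warning("%d panel SNPs absent from %s", gm.n_missing_columns, path)
    return gm


def write_dosage_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the delimited dosage-matrix interchange format (rsid header, NA for missing)."""
    df = gm.to_dosage_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


# ---------------------------------------------------------------------------
# Encoding


ENCODINGS = ("count", "beta_weighted")


def encode(genotypes: GenotypeMatrix, scheme: str = "count") -> FeatureMatrix:
    """Encode dosages as model features.

    ``count`` is the identity on dosages; ``beta_weighted`` multiplies each
    column by that SNP's beta.  Genotypes must be fully imputed first.
    """
    if scheme not in ENCODINGS:
        raise ValueError(f"unknown encoding {scheme!r}; choose from {ENCODINGS}")
    if genotypes.has_missing:
        raise ValueError(
            "genotypes contain missing entries; run hwe.impute before encoding"
        )
    values = genotypes.dosages.copy()
    if scheme == "beta_weighted":
        values = values * genotypes.panel.betas[np.newaxis, :]
    return FeatureMatrix(
        values=values,
        feature_names=list(genotypes.panel.rsids),
        encoding=scheme,
        subject_ids=list(genotypes.subject_ids),
    )
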